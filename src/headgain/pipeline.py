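"""In-silico replication of the two head-rotation compensation experiments.

Experiment 1 (trained head speed): each simulated listener runs, at each of
three trained speeds (20/60/100 deg/s), 4 blocks x (6 movement gains x 5
replications) = 120 trials per psychometric function, 360 per listener, with
gains -0.5..+0.75 in 0.25 steps randomized within block.

Experiment 2 (eccentricity): the listener faces the speaker at +45 deg of the
arc; sounds are confined to +/-20 deg windows fixed to the array around
eccentricities 0/45/90 deg (to the listener's left), 2 sessions x (9 gains x
10 replications) = 180 trials per eccentricity with gains -0.4..+0.4 in 0.1
steps.

Every trial simulates a head trace, renders the motion-contingent stimulus
(verifying it was ever audible), draws the observer's judgment, and records
the realized RMS head speed from the smoothed trace.  All randomness flows
from one root seed through named substreams, so identical configurations
give byte-identical trial streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinematics import HeadTrace, TrajectorySpec, simulate_trajectory, smooth_trace, velocity, rms_speed
from .observers import BayesObserver, LinearObserver, simulate_response
from .psychometrics import TrialRecord, aggregate, apply_outlier_rule, fit_probit, trials_to_frame
from .stimulus import (
    AudibilityWindow,
    SpeakerArray,
    render_trial,
)

__all__ = [
    "EngineConfig",
    "TrajectoryConfig",
    "ExperimentConfig",
    "default_exp1_config",
    "default_exp2_config",
    "load_config",
    "save_config",
    "observer_from_config",
    "build_design",
    "run_trial",
    "run_experiment",
    "ExperimentResult",
]

EXP1_GAINS = tuple(np.round(np.arange(-0.5, 0.751, 0.25), 10))   # 6 gains
EXP2_GAINS = tuple(np.round(np.arange(-0.4, 0.401, 0.1), 10))    # 9 gains


@dataclass(frozen=True)
class EngineConfig:
    """Stimulus-engine constants (array geometry, gating, ramp, start jitter)."""

    n_speakers: int = 23
    spacing_deg: float = 7.5
    envelope_sd_deg: float = 3.75
    fs: float = 240.0
    gate_tau: float = 0.050
    gate_threshold: float = 5.0
    ramp_dur: float = 0.5
    start_jitter_deg: float = 7.5

    @property
    def array(self) -> SpeakerArray:
        return SpeakerArray(self.n_speakers, self.spacing_deg)


@dataclass(frozen=True)
class TrajectoryConfig:
    excursion_half: float = 30.0
    speed_jitter_cv: float = 0.1
    turnaround_smoothing: float = 0.1
    sweeps_per_trial: int = 2


@dataclass(frozen=True)
class ExperimentConfig:
    """Full design + engine + observer configuration for one experiment."""

    experiment: str = "exp1"                      # "exp1" | "exp2"
    conditions: tuple = (20.0, 60.0, 100.0)       # speeds (exp1) or eccentricities (exp2)
    gains: tuple = EXP1_GAINS
    n_blocks: int = 4
    reps_per_block: int = 5
    n_listeners: int = 12
    observer: dict = field(
        default_factory=lambda: {
            "type": "bayes",
            "sigma_e": 4.73,
            "sigma_r": 2.0,
            "sigma_p": 10.0,
            "sigma_m": 0.25,
            "lapse": 0.02,
        }
    )
    engine: EngineConfig = field(default_factory=EngineConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    exp2_boresight_deg: float = 45.0
    exp2_window_half_deg: float = 20.0
    exp2_head_speed: float = 60.0
    seed: int = 0
    outlier_rule: bool = False
    outlier_n_sd: float = 10.0
    # per-eccentricity multiplier on sigma_m (exp2 precision knob; off = all 1)
    sigma_m_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be 'exp1' or 'exp2'")
        if self.n_blocks < 1 or self.reps_per_block < 1 or self.n_listeners < 1:
            raise ValueError("design counts must be >= 1")

    @property
    def trials_per_condition(self) -> int:
        return self.n_blocks * self.reps_per_block * len(self.gains)

    @property
    def trials_per_listener(self) -> int:
        return self.trials_per_condition * len(self.conditions)

    @property
    def reps_per_gain(self) -> int:
        return self.n_blocks * self.reps_per_block


def default_exp1_config(**overrides) -> ExperimentConfig:
    """Experiment 1 defaults: 3 trained speeds, 6 gains x 20 reps = 120/condition."""
    return ExperimentConfig(**overrides)


def default_exp2_config(**overrides) -> ExperimentConfig:
    """Experiment 2 defaults: 3 eccentricities, 9 gains x 20 reps = 180/condition."""
    base = dict(
        experiment="exp2",
        conditions=(0.0, 45.0, 90.0),
        gains=EXP2_GAINS,
        n_blocks=2,        # two sessions of 90 trials
        reps_per_block=10,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def save_config(config: ExperimentConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["conditions"] = list(d["conditions"])
    d["gains"] = [float(g) for g in d["gains"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["engine"] = EngineConfig(**d.get("engine", {}))
    d["trajectory"] = TrajectoryConfig(**d.get("trajectory", {}))
    d["conditions"] = tuple(d.get("conditions", ()))
    d["gains"] = tuple(d.get("gains", ()))
    return ExperimentConfig(**d)


def observer_from_config(spec: dict, rng: np.random.Generator | None = None):
    """Build an observer from a config dict.

    ``type`` selects "linear" (e, r) or "bayes" (sigma_e, sigma_r, sigma_p).
    Optional population keys (``e_sd`` for linear, ``sigma_e_sd`` for bayes,
    ``log_sigma_m_sd`` for either) draw per-listener parameters with ``rng``.
    """
    spec = dict(spec)
    kind = spec.pop("type")
    e_sd = spec.pop("e_sd", 0.0)
    sigma_e_sd = spec.pop("sigma_e_sd", 0.0)
    log_sigma_m_sd = spec.pop("log_sigma_m_sd", 0.0)
    if rng is not None and log_sigma_m_sd > 0:
        spec["sigma_m"] = spec.get("sigma_m", 0.25) * np.exp(log_sigma_m_sd * rng.standard_normal())
    if kind == "linear":
        if rng is not None and e_sd > 0:
            spec["e"] = spec["e"] + e_sd * rng.standard_normal()
        return LinearObserver(**spec)
    if kind == "bayes":
        if rng is not None and sigma_e_sd > 0:
            spec["sigma_e"] = abs(spec["sigma_e"] + sigma_e_sd * rng.standard_normal())
        return BayesObserver(**spec)
    raise ValueError(f"unknown observer type {kind!r}")


def build_design(config: ExperimentConfig, listener_index: int) -> list[tuple[float, float]]:
    """Ordered (condition, gain) trial list for one listener.

    Gains are replicated ``reps_per_block`` times and shuffled within each
    block; blocks run consecutively within a condition.  Deterministic given
    the config seed and listener index.
    """
    rng = np.random.default_rng([config.seed, listener_index, 0])
    trials: list[tuple[float, float]] = []
    for cond in config.conditions:
        for _ in range(config.n_blocks):
            block = np.repeat(config.gains, config.reps_per_block)
            rng.shuffle(block)
            trials.extend((float(cond), float(g)) for g in block)
    return trials


def _trial_geometry(config: ExperimentConfig, condition: float):
    """Head-trace centre, source reference azimuth, window and target speed."""
    if config.experiment == "exp1":
        return 0.0, 0.0, None, condition
    # exp2: listener faces the +boresight speaker; eccentricities lie to the
    # left, so world azimuth = boresight - eccentricity; window fixed there
    center = config.exp2_boresight_deg
    ref = config.exp2_boresight_deg - condition
    window = AudibilityWindow(ref, config.exp2_window_half_deg)
    return center, ref, window, config.exp2_head_speed


def run_trial(
    config: ExperimentConfig,
    observer,
    condition: float,
    gain: float,
    head_direction: int,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one trial end to end and return its record.

    A head trace of ``sweeps_per_trial`` sweeps is simulated at the
    condition's target speed, the stimulus is rendered (start azimuth jittered
    +/-7.5 deg about the reference), audibility is verified (one re-draw is
    allowed before erroring), the observer's judgment is drawn, and the RMS
    speed of the smoothed trace is recorded.
    """
    head_center, source_ref, window, target_speed = _trial_geometry(config, condition)
    tr = config.trajectory
    spec = TrajectorySpec(
        target_speed=target_speed,
        excursion_half=tr.excursion_half,
        duration=tr.sweeps_per_trial * 2 * tr.excursion_half / target_speed,
        speed_jitter_cv=tr.speed_jitter_cv,
        turnaround_smoothing=tr.turnaround_smoothing,
        fs=config.engine.fs,
    )
    eng = config.engine
    for attempt in range(2):
        trace = simulate_trajectory(spec, rng)
        yaw = head_center + head_direction * (trace.yaw_deg - trace.yaw_deg[0]) - head_direction * tr.excursion_half
        # trace starts at -excursion_half and sweeps right first; head_direction
        # flips it and head_center recentres it (exp2 boresight)
        start_mu = source_ref + rng.uniform(-eng.start_jitter_deg, eng.start_jitter_deg)
        rendered = render_trial(
            eng.array,
            yaw,
            gain,
            start_mu,
            fs=eng.fs,
            sigma_deg=eng.envelope_sd_deg,
            window=window,
            gate_tau=eng.gate_tau,
            gate_threshold=eng.gate_threshold,
            ramp_dur=eng.ramp_dur,
        )
        if rendered.ever_audible:
            break
        if attempt == 1:
            raise RuntimeError(
                f"stimulus never audible after re-draw (condition={condition}, gain={gain})"
            )
    sigma_mult = float(config.sigma_m_multipliers.get(condition, 1.0))
    obs = observer
    if sigma_mult != 1.0:
        obs = dataclasses.replace(observer, sigma_m=observer.sigma_m * sigma_mult)
    response = simulate_response(obs, gain, head_direction, rng)
    rms = rms_speed(velocity(smooth_trace(HeadTrace(fs=eng.fs, yaw_deg=yaw))))
    return TrialRecord(
        listener_id="",  # filled by the caller
        condition=_condition_label(config, condition),
        gain=gain,
        response=response,
        rms_speed=rms,
    )


def _condition_label(config: ExperimentConfig, condition: float) -> str:
    unit = "degs" if config.experiment == "exp1" else "deg"
    return f"{condition:g}{unit}"


@dataclass
class ExperimentResult:
    trials: pd.DataFrame
    fits: pd.DataFrame
    group_table: pd.DataFrame
    config: ExperimentConfig
    excluded_listeners: list


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full experiment: all listeners, conditions and trials.

    Per listener x condition the trials are fit with the ML probit; the group
    table reports per-condition means and SEs of PSE and threshold plus mean
    realized RMS speed, over converged fits (the whole-listener outlier rule
    applies only if enabled in the config).  If ``out_dir`` is given, writes
    trials.csv, fits.csv, group_table.csv and manifest.json there.
    """
    records = []
    for i in range(config.n_listeners):
        listener_id = f"L{i + 1:02d}"
        obs_rng = np.random.default_rng([config.seed, i, 1])
        observer = observer_from_config(config.observer, obs_rng)
        trial_rng = np.random.default_rng([config.seed, i, 2])
        for j, (cond, g) in enumerate(build_design(config, i)):
            head_direction = 1 if j % 2 == 0 else -1  # alternate start direction
            rec = run_trial(config, observer, cond, g, head_direction, trial_rng)
            records.append(dataclasses.replace(rec, listener_id=listener_id))
    trials = trials_to_frame(records)

    fit_rows = []
    for (lid, cond), sub in trials.groupby(["listener_id", "condition"], sort=False):
        fit = fit_probit(aggregate(sub))
        fit_rows.append(
            dict(
                listener_id=lid,
                condition=cond,
                pse=fit.pse,
                sd=fit.sd,
                loglik=fit.loglik,
                converged=fit.converged,
                n_trials=fit.n_trials,
                mean_rms_speed=float(sub["rms_speed"].mean()),
            )
        )
    fits = pd.DataFrame(fit_rows)

    usable = fits[fits["converged"]]
    excluded: list = []
    if config.outlier_rule and len(usable) > 1:
        usable, excluded = apply_outlier_rule(usable, value="pse", n_sd=config.outlier_n_sd)

    group_rows = []
    for cond, sub in usable.groupby("condition", sort=False):
        n = len(sub)
        group_rows.append(
            dict(
                condition=cond,
                mean_pse=float(sub["pse"].mean()),
                se_pse=float(sub["pse"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                mean_threshold=float(sub["sd"].mean()),
                se_threshold=float(sub["sd"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                mean_rms_speed=float(sub["mean_rms_speed"].mean()),
                n_listeners=n,
            )
        )
    group = pd.DataFrame(group_rows)

    result = ExperimentResult(trials=trials, fits=fits, group_table=group, config=config,
                              excluded_listeners=excluded)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        group.to_csv(out / "group_table.csv", index=False)
        manifest = {
            "package": "headgain",
            "version": __version__,
            "numpy": np.__version__,
            "seed": config.seed,
            "excluded_listeners": excluded,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=float)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
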