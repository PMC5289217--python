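"""Motion-contingent stimulus engine.

A virtual sound source is rendered on an arc of loudspeakers by sweeping a
Gaussian amplitude envelope across the array.  The envelope centre is updated
every head-tracker sample by a signed *movement gain* ``m`` applied to the
instantaneous head yaw velocity,

    mu[t] = mu[t-1] + m * v[t] * dt,

so ``m = +1`` yokes the source to the head, ``m = 0`` leaves it fixed in the
world and negative gains move it against the head.  Audibility is gated on a
leaky-integrated head speed (the source is silent while the head is still),
multiplied by a linear onset ramp each time sound resumes, and optionally by
a spatial window fixed to the array.

The engine emits per-speaker gain tracks, not audio waveforms: every analysis
downstream lives in gain/position space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeakerArray",
    "EnvelopeState",
    "AudibilityWindow",
    "RenderedTrial",
    "envelope_gains",
    "update_position",
    "integrate_position",
    "leaky_gate",
    "onset_ramp",
    "ramp_track",
    "apply_window",
    "render_trial",
    "write_gain_track",
    "read_gain_track",
]

#: engine defaults: tracker rate, gate time constant / threshold, onset ramp
DEFAULT_FS = 240.0
DEFAULT_GATE_TAU = 0.050       # s
DEFAULT_GATE_THRESHOLD = 5.0   # deg/s on the integrated speed
DEFAULT_RAMP_DUR = 0.5         # s
DEFAULT_ENVELOPE_SD = 3.75     # deg, half the speaker spacing


@dataclass(frozen=True)
class SpeakerArray:
    """Geometry of a horizontal loudspeaker arc, symmetric about 0 deg.

    Positions are arithmetic with step ``spacing_deg`` and centred on the
    middle speaker; the default is 23 speakers spaced 7.5 deg apart, i.e. a
    half-extent of +/-82.5 deg.
    """

    n_speakers: int = 23
    spacing_deg: float = 7.5

    def __post_init__(self) -> None:
        if self.n_speakers < 1:
            raise ValueError("n_speakers must be >= 1")
        if self.spacing_deg <= 0:
            raise ValueError("spacing_deg must be > 0")

    @property
    def half_extent_deg(self) -> float:
        return (self.n_speakers - 1) / 2 * self.spacing_deg

    @property
    def positions_deg(self) -> np.ndarray:
        """Ordered speaker azimuths in degrees (left negative)."""
        return (np.arange(self.n_speakers) - (self.n_speakers - 1) / 2) * self.spacing_deg


@dataclass(frozen=True)
class EnvelopeState:
    """Gaussian source envelope: world-frame centre and SD, both in degrees."""

    mu_deg: float
    sigma_deg: float = DEFAULT_ENVELOPE_SD

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_deg):
            raise ValueError("mu_deg must be finite")
        if not (np.isfinite(self.sigma_deg) and self.sigma_deg > 0):
            raise ValueError("sigma_deg must be finite and > 0")


@dataclass(frozen=True)
class AudibilityWindow:
    """Spatial audibility window fixed to the array (centre +/- half-width)."""

    center_deg: float
    half_width_deg: float = 20.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.half_width_deg) and self.half_width_deg > 0):
            raise ValueError("half_width_deg must be finite and > 0")


def envelope_gains(array: SpeakerArray, state: EnvelopeState) -> np.ndarray:
    """Per-speaker amplitude gains of the Gaussian source envelope.

    The gain of the speaker at azimuth ``x`` is ``exp(-(x - mu)^2 / (2 sigma^2))``,
    with no normalisation.  Speakers beyond the arc simply do not exist, so an
    envelope pushed past the edge loses energy off the end (no wraparound).
    """
    x = array.positions_deg
    z = (x - state.mu_deg) / state.sigma_deg
    return np.exp(-0.5 * z * z)


def update_position(mu_prev: float, m: float, v_t: float, dt: float) -> float:
    """One-sample envelope-centre update: ``mu_prev + m * v_t * dt``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return mu_prev + m * v_t * dt


def integrate_position(start_mu: float, m: float, velocity: np.ndarray, dt: float) -> np.ndarray:
    """Envelope-centre trajectory for a whole trial (vectorised update rule).

    ``out[0] == start_mu`` (the position before any movement has been applied)
    and ``out[k] = start_mu + m * dt * sum(velocity[1..k])``: velocity sample 0
    is not integrated, matching the per-sample recurrence where the first
    update uses the velocity at the first *new* sample.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(velocity, dtype=float)
    mu = np.empty_like(v)
    mu[0] = start_mu
    mu[1:] = start_mu + m * dt * np.cumsum(v[1:])
    return mu


def leaky_gate(
    speed: np.ndarray,
    fs: float = DEFAULT_FS,
    tau: float = DEFAULT_GATE_TAU,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> np.ndarray:
    """Audibility mask from leaky-integrated head speed.

    The instantaneous (non-negative) head speed is passed through a first-order
    exponential smoother with time constant ``tau`` seconds, discretised
    exactly as ``y[n] = a*y[n-1] + (1-a)*s[n]`` with ``a = exp(-1/(fs*tau))``;
    the stimulus is audible wherever the smoothed speed exceeds ``threshold``.
    A still head (all-zero speed) is therefore never audible, and brief
    single-sample tracker spikes are suppressed.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    s = np.abs(np.asarray(speed, dtype=float))
    if s.size == 0:
        return np.zeros(0, dtype=bool)
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (fs * tau))
    y = lfilter([1.0 - a], [1.0, -a], s)
    return y > threshold


def leaky_integrated_speed(
    speed: np.ndarray, fs: float = DEFAULT_FS, tau: float = DEFAULT_GATE_TAU
) -> np.ndarray:
    """The gate's smoothed-speed series itself (useful for tests/diagnostics)."""
    s = np.abs(np.asarray(speed, dtype=float))
    if s.size == 0:
        return np.zeros(0)
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (fs * tau))
    return lfilter([1.0 - a], [1.0, -a], s)


def onset_ramp(t_since_audible: float, ramp_dur: float = DEFAULT_RAMP_DUR) -> float:
    """Linear onset multiplier ``min(1, t/ramp_dur)``; resets on each onset."""
    if ramp_dur <= 0:
        raise ValueError("ramp_dur must be > 0")
    if t_since_audible < 0:
        raise ValueError("t_since_audible must be >= 0")
    return min(1.0, t_since_audible / ramp_dur)


def ramp_track(audible: np.ndarray, fs: float = DEFAULT_FS, ramp_dur: float = DEFAULT_RAMP_DUR) -> np.ndarray:
    """Per-sample ramp multiplier, restarting at every audibility onset.

    Within each contiguous audible segment the multiplier rises linearly from
    0 at the onset sample to 1 after ``ramp_dur`` seconds; it is 0 wherever
    the mask is off.
    """
    if ramp_dur <= 0:
        raise ValueError("ramp_dur must be > 0")
    audible = np.asarray(audible, dtype=bool)
    n = audible.size
    ramp = np.zeros(n)
    if n == 0:
        return ramp
    # index of the most recent onset at each audible sample
    onsets = np.flatnonzero(audible & ~np.concatenate(([False], audible[:-1])))
    for start in onsets:
        end = start
        while end < n and audible[end]:
            end += 1
        t = (np.arange(end - start)) / fs
        ramp[start:end] = np.minimum(1.0, t / ramp_dur)
    return ramp


def apply_window(mu: float | np.ndarray, window: AudibilityWindow | None) -> np.ndarray | bool:
    """True where the envelope centre lies inside the window (boundary inclusive)."""
    if window is None:
        return np.ones_like(np.asarray(mu, dtype=float), dtype=bool) if np.ndim(mu) else True
    return np.abs(np.asarray(mu, dtype=float) - window.center_deg) <= window.half_width_deg


@dataclass
class RenderedTrial:
    """Frame-by-frame rendering of one trial.

    ``gains`` holds the raw envelope gains (one column per speaker);
    ``effective_gains`` additionally carries the gate, ramp and window, so a
    row is all-zero whenever the stimulus is inaudible.
    """

    t: np.ndarray
    mu_deg: np.ndarray
    audible: np.ndarray
    ramp: np.ndarray
    gains: np.ndarray
    array: SpeakerArray = field(default_factory=SpeakerArray)

    @property
    def effective_gains(self) -> np.ndarray:
        return self.gains * (self.audible * self.ramp)[:, None]

    @property
    def ever_audible(self) -> bool:
        return bool(self.audible.any())


def render_trial(
    array: SpeakerArray,
    head_yaw_deg: np.ndarray,
    m: float,
    start_mu: float,
    *,
    fs: float = DEFAULT_FS,
    sigma_deg: float = DEFAULT_ENVELOPE_SD,
    window: AudibilityWindow | None = None,
    gate_tau: float = DEFAULT_GATE_TAU,
    gate_threshold: float = DEFAULT_GATE_THRESHOLD,
    ramp_dur: float = DEFAULT_RAMP_DUR,
) -> RenderedTrial:
    """Render one trial: envelope trajectory, audibility and per-speaker gains.

    The envelope centre starts at ``start_mu`` and advances each tracker
    sample by ``m`` times the instantaneous head velocity (first difference of
    the yaw trace, as in the real-time system).  Audibility combines the
    leaky-integrated speed gate, the optional spatial window on the envelope
    centre, and the linear onset ramp (which restarts whenever sound resumes).
    """
    yaw = np.asarray(head_yaw_deg, dtype=float)
    if yaw.ndim != 1 or yaw.size < 2:
        raise ValueError("head_yaw_deg must be a 1-D trace with >= 2 samples")
    EnvelopeState(start_mu, sigma_deg)  # validate
    dt = 1.0 / fs
    # real-time velocity: difference between the current sample and the one
    # before; v[0] = 0 (no movement has yet been observed)
    v = np.empty_like(yaw)
    v[0] = 0.0
    v[1:] = np.diff(yaw) * fs
    mu = integrate_position(start_mu, m, v, dt)
    gate = leaky_gate(v, fs=fs, tau=gate_tau, threshold=gate_threshold)
    in_window = apply_window(mu, window)
    audible = gate & in_window
    ramp = ramp_track(audible, fs=fs, ramp_dur=ramp_dur)
    x = array.positions_deg
    z = (x[None, :] - mu[:, None]) / sigma_deg
    gains = np.exp(-0.5 * z * z)
    t = np.arange(yaw.size) * dt
    return RenderedTrial(t=t, mu_deg=mu, audible=audible, ramp=ramp, gains=gains, array=array)


def write_gain_track(trial: RenderedTrial, path) -> None:
    """Write a rendered trial as CSV: time_s, mu_deg, audible, ramp, gain_01.."""
    cols = {f"gain_{i + 1:02d}": trial.gains[:, i] for i in range(trial.gains.shape[1])}
    df = pd.DataFrame(
        {
            "time_s": trial.t,
            "mu_deg": trial.mu_deg,
            "audible": trial.audible.astype(int),
            "ramp": trial.ramp,
            **cols,
        }
    )
    df.to_csv(path, index=False)


def read_gain_track(path) -> pd.DataFrame:
    """Read a gain-track CSV written by :func:`write_gain_track`."""
    return pd.read_csv(path)
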