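"""Cumulative-Gaussian psychometric fitting and group statistics.

Each listener x condition yields a set of with/against judgments at a fixed
grid of movement gains (method of constant stimuli).  The proportion of
"with" responses is modelled as ``P(with | g) = Phi((g - pse) / sd)`` and fit
by maximum likelihood under the binomial likelihood — probit analysis.  The
fitted mean is the point of subjective equality (the 50% point) and the
fitted SD is the discrimination threshold (the gain difference between the
84.1% and 50% points).  No lapse parameter is fit: the function has exactly
two parameters, and robustness to generator lapses is a property to test,
not to patch.

Internally the fit runs on the linear predictor ``Phi(a + b*g)`` by Fisher
scoring (the natural ML parametrization; ``pse = -a/b``, ``sd = 1/|b|``),
which handles 0%/100% cells without ad-hoc corrections.  Degenerate tables —
all-identical responses, perfect separation — are flagged ``converged=False``
rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

__all__ = [
    "TrialRecord",
    "PsychometricFit",
    "aggregate",
    "fit_probit",
    "fit_trials",
    "bootstrap_ci",
    "group_stats",
    "apply_outlier_rule",
    "trials_to_frame",
]

MIN_SD = 1e-4  # separation guard: slopes steeper than 1/MIN_SD are non-converged


@dataclass(frozen=True)
class TrialRecord:
    """One with/against judgment."""

    listener_id: str
    condition: str
    gain: float
    response: str  # "with" | "against"
    rms_speed: float

    def __post_init__(self) -> None:
        if self.response not in ("with", "against"):
            raise ValueError("response must be 'with' or 'against'")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")


@dataclass(frozen=True)
class PsychometricFit:
    pse: float
    sd: float
    loglik: float
    converged: bool
    n_trials: int


def trials_to_frame(trials) -> pd.DataFrame:
    """TrialRecords (or an equivalent DataFrame) -> canonical DataFrame."""
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame(
        {
            "listener_id": [t.listener_id for t in trials],
            "condition": [t.condition for t in trials],
            "gain": [t.gain for t in trials],
            "response": [t.response for t in trials],
            "rms_speed": [t.rms_speed for t in trials],
        }
    )


def aggregate(trials) -> pd.DataFrame:
    """Per-gain response counts: columns gain, n_with, n_total (gain-sorted)."""
    df = trials_to_frame(trials)
    if len(df) == 0:
        raise ValueError("no trials to aggregate")
    grouped = (
        df.assign(with_flag=(df["response"] == "with").astype(int))
        .groupby("gain", sort=True)
        .agg(n_with=("with_flag", "sum"), n_total=("with_flag", "size"))
        .reset_index()
    )
    return grouped


def _probit_loglik(a: float, b: float, g: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(ndtr(a + b * g), 1e-12, 1 - 1e-12)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_probit(table: pd.DataFrame, max_iter: int = 100, tol: float = 1e-10) -> PsychometricFit:
    """ML cumulative-Gaussian fit to a (gain, n_with, n_total) table.

    Fisher scoring on (intercept, slope); starting values come from a
    weighted regression of probit-transformed proportions (with clipped
    0%/100% cells), which the scoring iterations then refine to the exact
    binomial ML solution.  Returns ``converged=False`` (never raises) for
    degenerate tables: fewer than two distinct gains, all-identical
    responses, or perfect separation driving the slope out of range.
    """
    return _fit_probit_arrays(
        table["gain"].to_numpy(dtype=float),
        table["n_with"].to_numpy(dtype=float),
        table["n_total"].to_numpy(dtype=float),
        max_iter=max_iter,
        tol=tol,
    )


def _fit_probit_arrays(
    g: np.ndarray, k: np.ndarray, n: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> PsychometricFit:
    n_trials = int(n.sum())
    bad = PsychometricFit(pse=np.nan, sd=np.nan, loglik=np.nan, converged=False, n_trials=n_trials)
    if len(g) < 2 or n_trials == 0:
        return bad
    if k.sum() == 0 or k.sum() == n.sum():
        return bad  # all-identical responses: the 50% point is unidentified

    # transformed-proportion starting values
    p0 = np.clip(k / n, 0.5 / np.maximum(n, 1), 1 - 0.5 / np.maximum(n, 1))
    z = ndtri(p0)
    w0 = n
    X = np.column_stack([np.ones_like(g), g])
    beta = np.linalg.lstsq(X * w0[:, None], z * w0, rcond=None)[0]

    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
        phi = np.exp(-0.5 * eta * eta) / np.sqrt(2 * np.pi)
        u = (k - n * p) * phi / (p * (1 - p))            # score wrt eta
        w = n * phi**2 / (p * (1 - p))                   # Fisher weights
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, X.T @ u)
        except np.linalg.LinAlgError:
            return bad
        beta = beta + step
        if not np.all(np.isfinite(beta)) or abs(beta[1]) > 1.0 / MIN_SD:
            return bad  # separation: slope diverging
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    a, b = beta
    if not converged or b == 0:
        return PsychometricFit(
            pse=-a / b if b != 0 else np.nan,
            sd=1.0 / abs(b) if b != 0 else np.nan,
            loglik=_probit_loglik(a, b, g, k, n),
            converged=False,
            n_trials=n_trials,
        )
    return PsychometricFit(
        pse=float(-a / b),
        sd=float(1.0 / abs(b)),
        loglik=_probit_loglik(a, b, g, k, n),
        converged=True,
        n_trials=n_trials,
    )


def fit_trials(trials) -> PsychometricFit:
    """Aggregate raw trials and fit in one step."""
    return fit_probit(aggregate(trials))


def bootstrap_ci(
    trials,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> dict:
    """Percentile bootstrap intervals for pse and sd.

    Responses are resampled with replacement *within* each gain level (the
    design is fixed; only the binomial outcomes are random), each resample is
    refit, and percentile intervals are taken over the converged fits.
    Non-converged resamples are skipped and reported as ``skip_rate``.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = aggregate(trials)
    g = table["gain"].to_numpy(dtype=float)
    k = table["n_with"].to_numpy(dtype=int)
    n = table["n_total"].to_numpy(dtype=int)
    phat = k / n
    pses, sds = [], []
    n_float = n.astype(float)
    for _ in range(n_boot):
        k_star = rng.binomial(n, phat).astype(float)
        fit = _fit_probit_arrays(g, k_star, n_float)
        if fit.converged:
            pses.append(fit.pse)
            sds.append(fit.sd)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    n_ok = len(pses)
    if n_ok == 0:
        return {"pse_ci": (np.nan, np.nan), "sd_ci": (np.nan, np.nan), "skip_rate": 1.0}
    return {
        "pse_ci": tuple(np.percentile(pses, [lo, hi])),
        "sd_ci": tuple(np.percentile(sds, [lo, hi])),
        "skip_rate": 1 - n_ok / n_boot,
    }


def group_stats(fits: pd.DataFrame, value: str = "pse") -> pd.DataFrame:
    """Per-condition mean, SE and one-sample t of listener values against 0.

    ``fits`` needs columns listener_id, condition and ``value``.  Conditions
    with all-identical values get SE 0, a ``degenerate`` flag and no finite t.
    Fewer than 2 listeners in any condition is an error (SE undefined).
    """
    rows = []
    for cond, sub in fits.groupby("condition", sort=True):
        x = sub[value].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 listeners; SE undefined")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        se = sd / np.sqrt(len(x))
        if sd == 0:
            rows.append(
                dict(condition=cond, mean=mean, se=0.0, t=np.inf if mean != 0 else 0.0,
                     p=np.nan, n=len(x), degenerate=True)
            )
            continue
        t, p = stats.ttest_1samp(x, 0.0)
        rows.append(dict(condition=cond, mean=mean, se=se, t=float(t), p=float(p),
                         n=len(x), degenerate=False))
    return pd.DataFrame(rows)


def apply_outlier_rule(fits: pd.DataFrame, value: str = "pse", n_sd: float = 10.0) -> tuple[pd.DataFrame, list]:
    """Drop whole listeners whose ``value`` lies more than ``n_sd`` SDs from
    the group mean (off by default in the pipeline; mirrors the whole-dataset
    exclusion convention).  Returns (kept, excluded listener ids).
    """
    x = fits[value].to_numpy(dtype=float)
    mu, sd = np.mean(x), np.std(x, ddof=1)
    if sd == 0:
        return fits, []
    out = fits.loc[np.abs(x - mu) > n_sd * sd, "listener_id"].unique().tolist()
    return fits[~fits["listener_id"].isin(out)], out
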