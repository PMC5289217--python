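"""Synthetic listeners: compensation models that turn a movement gain into a
with/against judgment.

Two accounts of incomplete compensation for head rotation are implemented.

Linear gain-mismatch observer.  With head velocity ``P``, the non-acoustic
("extracochlear") channel reports ``e*P`` and the acoustic image-motion
channel reports ``r*(g-1)*P`` for a source driven at movement gain ``g``
(image motion is ``(g-1)*P`` because a source at gain 1 is head-fixed).
Perceived world motion, in gain units, is

    perceived(g) = e + r*(g - 1),

so a physically stationary source (g = 0) appears to move at ``e - r``:
negative — against the head — whenever the extracochlear gain undershoots
the acoustic gain.  The point of subjective equality (PSE) solves
``perceived(g) = 0``: pse = 1 - e/r.  Decision noise ``sigma_m`` (SD in
gain units, one draw per trial) gives a cumulative-Gaussian psychometric
function with SD ``sigma_m / r``.

Bayesian shrinkage observer.  Each channel's speed estimate is the posterior
mean under a zero-centred slow-motion prior (SD ``sigma_p``) and a Gaussian
likelihood (SD ``sigma_e`` or ``sigma_r``), which shrinks the channel gain to
``sigma_p^2 / (sigma_p^2 + sigma^2)``.  A noisier channel is shrunk harder,
so unequal channel reliabilities reproduce the same signature e < r without
any fixed calibration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "LinearObserver",
    "BayesObserver",
    "ObserverPrediction",
    "effective_gains",
    "perceived_gain",
    "predict",
    "p_with",
    "simulate_response",
]


@dataclass(frozen=True)
class LinearObserver:
    """Gain-mismatch observer with fixed channel gains.

    e : extracochlear (self-motion) gain, dimensionless.
    r : acoustic image-motion gain, dimensionless, > 0.
    sigma_m : SD of trial-level noise on the perceived world-motion gain.
    lapse : probability of a random response.
    """

    e: float
    r: float = 1.0
    sigma_m: float = 0.25
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")
        if not (0 <= self.lapse < 1):
            raise ValueError("lapse must be in [0, 1)")


@dataclass(frozen=True)
class BayesObserver:
    """Slow-motion-prior observer; channel gains arise from shrinkage.

    sigma_e, sigma_r : likelihood SDs (deg/s) of the extracochlear and
        acoustic channels.
    sigma_p : SD (deg/s) of the zero-centred prior over world speeds.
    sigma_m, lapse : decision noise (gain units) and lapse rate, as above.
    """

    sigma_e: float
    sigma_r: float
    sigma_p: float
    sigma_m: float = 0.25
    lapse: float = 0.02

    def __post_init__(self) -> None:
        for name in ("sigma_e", "sigma_r", "sigma_p", "sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.lapse < 1):
            raise ValueError("lapse must be in [0, 1)")


@dataclass(frozen=True)
class ObserverPrediction:
    """Analytic psychometric parameters implied by an observer."""

    pse: float
    threshold: float


def effective_gains(obs: BayesObserver) -> tuple[float, float]:
    """Shrinkage gains (e_eff, r_eff) of the two channels.

    Posterior-mean readout of a Gaussian likelihood under a zero-mean
    Gaussian prior multiplies each channel by sigma_p^2/(sigma_p^2+sigma^2);
    a flat prior (sigma_p -> inf) recovers veridical unit gains.
    """
    sp2 = obs.sigma_p**2
    e_eff = sp2 / (sp2 + obs.sigma_e**2)
    r_eff = sp2 / (sp2 + obs.sigma_r**2)
    return e_eff, r_eff


def _linear_form(obs: LinearObserver | BayesObserver) -> LinearObserver:
    """Reduce any observer to its equivalent (e, r, sigma_m, lapse)."""
    if isinstance(obs, BayesObserver):
        e_eff, r_eff = effective_gains(obs)
        return LinearObserver(e=e_eff, r=r_eff, sigma_m=obs.sigma_m, lapse=obs.lapse)
    return obs


def perceived_gain(obs: LinearObserver | BayesObserver, g) -> np.ndarray | float:
    """Mean perceived world-motion gain ``e + r*(g - 1)`` (affine in g, slope r)."""
    lin = _linear_form(obs)
    return lin.e + lin.r * (np.asarray(g, dtype=float) - 1.0)


def predict(obs: LinearObserver | BayesObserver) -> ObserverPrediction:
    """Analytic PSE ``1 - e/r`` and threshold ``sigma_m / r``.

    The PSE is the gain nulling the mean percept; the threshold is the SD of
    the implied cumulative-Gaussian psychometric function, i.e. the gain step
    from the 50% to the 84.1% point.
    """
    lin = _linear_form(obs)
    return ObserverPrediction(pse=1.0 - lin.e / lin.r, threshold=lin.sigma_m / lin.r)


def p_with(obs: LinearObserver | BayesObserver, g) -> np.ndarray | float:
    """Probability of a "with the head" judgment at movement gain ``g``.

    ``lapse/2 + (1-lapse) * Phi((g - pse) / (sigma_m/r))``; by construction
    the 50% point sits at the PSE and the 84.1% point one threshold above it.
    """
    pred = predict(obs)
    lin = _linear_form(obs)
    core = norm.cdf((np.asarray(g, dtype=float) - pred.pse) / (lin.sigma_m / lin.r))
    return lin.lapse / 2 + (1 - lin.lapse) * core


def simulate_response(
    obs: LinearObserver | BayesObserver,
    g: float,
    head_direction: int,
    rng: np.random.Generator,
) -> str:
    """Draw one with/against judgment at movement gain ``g``.

    ``head_direction`` (+1 rightward first sweep, -1 leftward) must be a unit
    sign; responses are sign-referenced to it, so the psychometric function
    in g is direction-invariant and the draw reduces to a Bernoulli trial on
    :func:`p_with`.
    """
    if head_direction not in (+1, -1):
        raise ValueError("head_direction must be +1 or -1")
    return "with" if rng.random() < p_with(obs, g) else "against"
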