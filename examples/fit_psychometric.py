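"""Fit a psychometric function to one simulated listener.

Draws the standard 120-trial method-of-constant-stimuli session (6 movement
gains x 20 judgments) from a noisy, incompletely compensating observer, fits
the maximum-likelihood cumulative Gaussian, and bootstraps uncertainty.
"""

import numpy as np

from headgain import LinearObserver, TrialRecord, aggregate, bootstrap_ci, fit_trials, p_with

rng = np.random.default_rng(3)
obs = LinearObserver(e=0.85, r=1.0, sigma_m=0.25, lapse=0.02)
gains = np.round(np.arange(-0.5, 0.751, 0.25), 10)

trials = []
for g in gains:
    for _ in range(20):
        resp = "with" if rng.random() < p_with(obs, g) else "against"
        trials.append(TrialRecord("L01", "60degs", float(g), resp, 60.0))

print(aggregate(trials).to_string(index=False))
fit = fit_trials(trials)
ci = bootstrap_ci(trials, n_boot=1000, seed=0)
print(f"\nfitted PSE = {fit.pse:.3f}  (95% CI {ci['pse_ci'][0]:.3f}..{ci['pse_ci'][1]:.3f})")
print(f"fitted threshold = {fit.sd:.3f}  (95% CI {ci['sd_ci'][0]:.3f}..{ci['sd_ci'][1]:.3f})")
print(f"generating observer: PSE 0.150, threshold 0.250")

# The fitted PSE is the movement gain the listener calls "with" half the
# time — their subjectively stationary source; the threshold (the fitted
# Gaussian SD) is the gain step from 50% to 84.1% "with".
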