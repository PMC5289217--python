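"""Run a compact in-silico replication of the trained-speed experiment.

Six simulated listeners (Bayesian slow-motion-prior observers, effective
compensation ratio 0.85) each complete the full design: 120 trials per
trained speed at 20/60/100 deg/s.  Every trial simulates a head trace,
renders the motion-contingent stimulus, and draws a with/against judgment;
fits and the group table are computed exactly as for real data.
"""

from headgain.pipeline import default_exp1_config, run_experiment

cfg = default_exp1_config(seed=0, n_listeners=6)
res = run_experiment(cfg)

print(res.group_table.round(4).to_string(index=False))
grand = res.fits.loc[res.fits.converged, "pse"].mean()
print(f"\ngrand-mean PSE: {grand:.3f} movement-gain units")
print("-> a stationary sound seems to move against the head; cancelling the")
print("   illusion takes ~15% of head velocity, i.e. ~85% compensation,")
print("   flat across trained speeds.")
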