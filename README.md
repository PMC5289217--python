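# headgain

Simulation and analysis toolkit for **head-contingent auditory motion
psychophysics**: measuring how completely the auditory system compensates
for the listener's own head rotation when judging whether a sound moves.

## The problem and the paradigm

When the head turns, the sound image sweeps across the ears even if the
source is fixed in the world. To perceive world-centred motion, the auditory
system must combine acoustic image motion with a non-acoustic
("extracochlear") estimate of head velocity — motor commands, proprioception,
vestibular signals. The paradigm implemented here makes a virtual source on a
loudspeaker arc move at a signed proportion *m* (the **movement gain**) of
the instantaneous head velocity:

    mu_t = mu_{t-1} + m * V_t * dt

where `mu` is the centre of a Gaussian amplitude envelope (SD 3.75°) swept
across 23 speakers spaced 7.5° apart, `V_t` the tracked head yaw velocity
(240 Hz), and `dt` the sample period. `m = +1` yokes the source to the head,
`m = 0` leaves it world-fixed, `m < 0` moves it against the head. Presenting
many gains in a method of constant stimuli and fitting a cumulative Gaussian
`P(with) = Φ((g − PSE)/σ)` to with/against judgments yields:

- **PSE** — the gain at the 50% point: the gain of a subjectively stationary
  source. 0 means perfect compensation; +1 means none.
- **threshold** — the fitted SD: the gain step from the 50% to the 84.1%
  point, a precision measure in movement-gain units.

Human listeners show PSE ≈ +0.15 (about 85% compensation): a stationary
sound appears to drift slightly *against* the head rotation, the auditory
analogue of the visual Filehne illusion. Two observer models reproduce this:

- **Linear gain-mismatch**: perceived world-motion gain `e + r(g − 1)`,
  with extracochlear gain `e` and acoustic image-motion gain `r`;
  `PSE = 1 − e/r`, threshold `σ_m/r`.
- **Bayesian shrinkage**: channel gains arise as `σ_p²/(σ_p² + σ²)` from a
  zero-centred slow-motion prior (SD `σ_p`) over each channel's Gaussian
  likelihood — the noisier channel is shrunk harder, yielding `e < r`
  without any fixed calibration error.

The package provides the full in-silico experiment: stimulus engine
(`headgain.stimulus`), synthetic head kinematics and tracker-style analysis
(`headgain.kinematics`), observer models (`headgain.observers`),
maximum-likelihood probit fitting and group statistics
(`headgain.psychometrics`), and an orchestration layer replicating the
trained-speed and eccentricity experiments end to end
(`headgain.pipeline`).

## Worked example

```
python examples/observer_predictions.py
```

```
linear observer e=0.85, r=1.0:
  perceived gain of a stationary source: -0.150  (negative = illusory motion against the head)
  PSE = 0.150, threshold = 0.250 gain units

Bayes observer sigma_e=4.73, sigma_r=2.0, sigma_p=10.0 deg/s:
  shrinkage gains: e_eff = 0.8172, r_eff = 0.9615
  PSE = 0.150, threshold = 0.260 gain units
```

An extracochlear gain 15% below the acoustic gain — imposed directly, or
produced by a slow-motion prior acting on a noisier extracochlear channel —
puts the PSE at +0.15: cancelling the illusory drift of a stationary source
takes a source moving at 15% of head velocity *with* the head.

Running the full simulated experiment recovers the same number from raw
with/against judgments:

```
python examples/run_experiment1.py
```

```
condition  mean_pse  se_pse  mean_threshold  se_threshold  mean_rms_speed  n_listeners
   20degs    0.1429  0.0247          0.3061        0.0184         19.6081            6
   60degs    0.1678  0.0158          0.2583        0.0127         56.9111            6
  100degs    0.1311  0.0290          0.2752        0.0093         92.0098            6

grand-mean PSE: 0.147 movement-gain units
```

Accuracy (PSE) and precision (threshold, in gain units) are flat across
trained head speeds, and the realized RMS head speeds track the trained
targets. The other examples cover stimulus rendering
(`render_stimulus.py`), head-trace simulation and analysis
(`head_kinematics.py`), and single-listener fitting with bootstrap
uncertainty (`fit_psychometric.py`).

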