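# Methods

This note documents the models, defaults and numerical choices behind
`headgain`, and what the synthetic experiments do and do not establish.

## Stimulus engine

A virtual source on a 23-speaker arc (7.5° spacing, ±82.5°) is a Gaussian
amplitude envelope over speaker azimuths, `exp(−(x−μ)²/2σ²)` with σ = 3.75°
(half the spacing) and no further normalisation. With σ = spacing/2 the
summed gain ripples by ~2.9% peak-to-peak as μ crosses a speaker gap — the
exact Poisson-summation value `4·exp(−2π²σ²/T²)` — which is the design point
at which three or more speakers are simultaneously active and level
modulation is small; widening σ to 5° drops the ripple below 1%. The
envelope may leave the physical arc, in which case energy simply falls off
the edge (no wraparound). The engine emits per-speaker gain tracks rather
than audio; all analysis lives in gain/position space.

The envelope centre advances every 240 Hz tracker sample by
`μ_t = μ_{t−1} + m·V_t·δt`, with `V_t` the first difference of the yaw trace
(as a real-time system would compute it) and `m` the signed movement gain
(positive = with the head). Trial start azimuth is drawn uniformly ±7.5°
about the reference. Audibility requires a moving head: the instantaneous
speed is passed through a first-order leaky integrator, discretised exactly
(`y_n = a·y_{n−1} + (1−a)·s_n`, `a = e^{−δt/τ}`, so the step response hits
1−e⁻¹ at t = τ), and gated at a threshold. τ = 50 ms and threshold = 5°/s
are package choices — small enough to pass the slowest trained speed
(20°/s) with a few tens of milliseconds of latency, large enough to
suppress single-sample tracker spikes. Sound intensity ramps on linearly
over 500 ms and the ramp restarts whenever audibility resumes. The
eccentricity experiment adds a spatial window fixed to the array
(±20° about the tested eccentricity, boundary inclusive — a measure-zero
convention fixed for reproducibility) that silences the source outside it.

## Head kinematics

Synthetic traces follow the training protocol: triangle-wave yaw between
±30° at per-sweep speeds `target·jitter`, jitter lognormal with unit mean
and CV 0.1 (positivity guaranteed; CV configurable), reversals rounded by a
100 ms moving average because human reversals are not instantaneous. A 12 s
sequence at 20/60/100°/s therefore contains 4/12/20 sweeps of 3/1/0.6 s.

Offline analysis mirrors tracker practice: Gaussian smoothing, central
differences (`np.gradient`; one-sided only at the two boundary samples), and
RMS speed `√mean(v²)`. The smoothing filter is specified by a
frequency-domain SD of 8 Hz, interpreted as a Gaussian frequency response,
i.e. a time-domain Gaussian kernel with σ_t = 1/(2π·8) ≈ 19.9 ms; at the
trained sweep rates this passes the motion essentially unattenuated. One
consequence worth knowing: the kernel rounds each velocity reversal over a
fixed ~2σ_t footprint, so the analysed RMS undershoots the commanded speed
by a fraction proportional to the sweep rate — ~0.8% at 20°/s, ~2.3% at
60°/s, ~3.9% at 100°/s — the same mild undershoot real head-tracking data
show at fast speeds.

## Observer models

Perceived world motion is the sum of the two channel estimates. For head
velocity `P` and movement gain `g`, the extracochlear channel contributes
`e·P` and the acoustic image-motion channel `r·(g−1)·P` (a source at gain 1
is head-fixed, so image motion is `(g−1)·P`); dividing by `P` puts the
percept in gain units: `perceived(g) = e + r(g−1)`. A stationary source
(`g = 0`) is perceived at `e − r` — negative, i.e. moving against the head,
whenever the extracochlear gain undershoots the acoustic gain. Solving
`perceived = 0` gives `PSE = 1 − e/r`; with trial-level Gaussian decision
noise σ_m on the perceived gain, the psychometric SD is σ_m/r. Only the
ratios matter: `(ke, kr, kσ_m)` leaves both quantities unchanged.

The Bayesian observer derives `e` and `r` instead of assuming them: each
channel's speed estimate is the posterior mean under a zero-centred
Gaussian slow-motion prior (SD σ_p) and a Gaussian likelihood (SD σ_e or
σ_r), giving shrinkage gains `σ_p²/(σ_p²+σ²)` per channel, read out
independently and summed. The default population (σ_p = 10, σ_r = 2,
σ_e = 4.73°/s) makes the extracochlear channel the noisier one and lands
the analytic PSE at 0.150 — ~85% compensation arising purely from
precision differences, with no fixed calibration error.

Decision noise is one draw per trial (σ_m = 0.25 gain units by default),
not per sweep: trial duration in the paradigm is self-paced, so a
trial-level aggregate is the tractable reading, and σ_m is kept fixed in
gain units (making thresholds a fixed proportion of head speed, a
Weber-like property). A 2% lapse rate is included in generation but never
in fitting; it inflates fitted thresholds slightly (~0.28 recovered vs 0.26
analytic) and stress-tests the 2-parameter fit realistically. Responses are
sign-referenced to head direction, so the psychometric function in `g` is
direction- and speed-invariant by construction.

## Psychometric fitting

The probit fit maximises the binomial log-likelihood of
`P(with|g) = Φ(a + b·g)` by Fisher scoring, started from a weighted
regression of probit-transformed proportions; `PSE = −a/b`, `sd = 1/|b|`.
This handles 0%/100% cells without corrections. Degenerate tables —
all-identical responses, a single gain level, or separation driving
`sd` below 10⁻⁴ — return `converged=False` rather than raising. The fit is
verified in the test suite against an exhaustive grid-search ML oracle and
against an independent IRLS probit-GLM implementation; Monte-Carlo at the
standard design (6 gains × 20 trials) puts PSE bias under 0.01 gain units.
Bootstrap intervals resample responses within gain levels (the design is
fixed) and report the skip rate of non-converged resamples; coverage at the
120-trial design is within a few points of nominal. Group summaries give
per-condition means, SEs and one-sample t-tests against 0; a whole-listener
outlier exclusion (>10 SD from the group mean) exists but is off by
default.

## Experiment pipeline

Experiment 1: per listener and trained speed, 4 blocks × (6 gains × 5
replications) randomized within block — 120 trials per psychometric
function, 360 per listener; gains −0.5..+0.75 in 0.25 steps. Experiment 2:
the listener faces the +45° speaker of the arc; eccentricities 0/45/90° lie
to the left (world azimuths +45/0/−45°) with ±20° windows fixed to the
array; 2 sessions × (9 gains × 10 replications) = 180 trials per
eccentricity, gains −0.4..+0.4 in 0.1 steps. Each simulated trial builds a
head trace of 2 full sweeps (a concrete stand-in for self-paced viewing;
configurable), alternating start direction trial to trial (the model is
direction-symmetric; alternation documents it), renders the stimulus,
verifies it was ever audible (one re-draw allowed), draws the judgment and
records the smoothed-trace RMS speed. The eccentricity experiment has no
trained speed; the default head-speed target is 60°/s, the middle trained
speed and the condition most comparable across experiments. A
per-eccentricity multiplier on σ_m exists to emulate declining precision at
eccentric azimuths but defaults to 1 (off), since the default observer is
location-invariant. All randomness flows from one root seed through named
substreams (design, observer, trials per listener), so identical
configurations produce identical outputs; runs can write trials.csv,
fits.csv, group_table.csv and a manifest.

## Problem sizes and what the tests show

The shipped simulations use the experiments' own sizes: 12 listeners, 120
trials per function, 240 Hz traces; a full replication runs in seconds, the
Monte-Carlo bias and bootstrap-coverage studies use 1000–1500 and 200
repeats respectively. Passing tests show that the pipeline recovers the
parameters of the observer that generated the data (grand-mean PSE within
±0.03 of the analytic 0.15 at the design's n) and that accuracy and
precision are flat across speeds when the generating observer is
speed-invariant. They do not validate the observer models against human
listeners: real data add between-listener parameter spread, serial
dependencies, tracker noise, front–back confusions and possible
speed-dependent noise, none of which the generator emulates (per-listener
parameter spread is available but off by default). Known limitations: no
audio-sample rendering or room acoustics; no dynamic evidence-accumulation
within trials; thresholds conflate extracochlear and acoustic noise, as
they do in the human data.
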