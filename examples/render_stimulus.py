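"""Render a motion-contingent sound source on the virtual speaker arc.

Builds a triangle-wave head trace (one 60 deg sweep at 60 deg/s), then
renders the Gaussian source envelope at movement gain 0.25: the source
drifts at a quarter of the head's velocity.
"""

import numpy as np

from headgain import SpeakerArray, render_trial
from headgain.kinematics import TrajectorySpec, simulate_trajectory

spec = TrajectorySpec(target_speed=60.0, duration=1.0, speed_jitter_cv=0.0)
trace = simulate_trajectory(spec, seed=0)

array = SpeakerArray()  # 23 speakers, 7.5 deg apart, +/-82.5 deg
out = render_trial(array, trace.yaw_deg, m=0.25, start_mu=0.0)

print(f"array: {array.n_speakers} speakers, half-extent {array.half_extent_deg} deg")
print(f"frames rendered: {out.t.size} at 240 Hz")
print(f"audible fraction: {out.audible.mean():.2f}")
print(f"envelope start -> end: {out.mu_deg[0]:+.2f} -> {out.mu_deg[-1]:+.2f} deg")
print(f"head start -> end:     {trace.yaw_deg[0]:+.2f} -> {trace.yaw_deg[-1]:+.2f} deg")
print(f"speakers above 1% gain at t=0: {np.count_nonzero(out.gains[0] > 0.01)}")

# The envelope moved ~0.25x the head's net displacement: with m = 0.25 the
# source follows a quarter of the head velocity, so a listener compensating
# perfectly would still judge it as moving "with" the head.
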