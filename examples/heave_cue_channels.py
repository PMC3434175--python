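"""Simulate the heave model and verify the cue-channel calibrations.

The aircraft responds to the collective input through dw/dt = Zw*w + Z0*Xc
(Z0 = 4.8; Zw = -0.1 hard, -0.5 easy).  The turbine audio level is linear in
Xc (3 dB excursion, 86-89 dB(A)); the motion platform receives the model
acceleration scaled to a 0.04 g/Xc peak slope and delayed by 80 ms.
"""

import numpy as np

from cuefidelity import CueChannelParams, HeaveParams, cue_channels, simulate_heave

params = HeaveParams(zw=-0.5)
cues = CueChannelParams()

# step response: the velocity settles at -Z0/Zw * Xc with time constant 1/|Zw|
xc = 0.5
trace = simulate_heave(params, np.full(3001, xc))
print(f"steady-state climb rate for Xc = {xc}: {trace.w[-1]:.3f} "
      f"(closed form {-params.z0 / params.zw * xc:.3f})")

# audio calibration over the full collective travel
sweep = np.linspace(-cues.collective_range / 2, cues.collective_range / 2, 301)
swept = cue_channels(simulate_heave(params, sweep), cues)
print(f"audio level range: {swept.audio_db.min():.1f} - {swept.audio_db.max():.1f} dB(A) "
      f"(excursion {swept.audio_db.max() - swept.audio_db.min():.1f} dB)")

# motion calibration across the five detection-task input magnitudes
peaks = []
for level in (0.1, 0.2, 0.3, 0.4, 0.5):
    u = np.zeros(600)
    u[100:] = level
    tr = cue_channels(simulate_heave(HeaveParams(zw=-0.1), u), cues)
    peaks.append(np.max(np.abs(tr.platform_accel_g)))
slope = np.polyfit((0.1, 0.2, 0.3, 0.4, 0.5), peaks, 1)[0]
print(f"peak platform acceleration slope: {slope:.4f} g per unit Xc")

u = np.zeros(600)
u[100:] = 0.3
tr = cue_channels(simulate_heave(HeaveParams(zw=-0.1), u), cues)
onset = int(np.argmax(np.abs(tr.platform_accel_g) > 1e-12))
print(f"motion channel latency: {(onset - 100) * 10:.0f} ms")
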