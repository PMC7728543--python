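"""Simulate a single game session and inspect its raw signal.

A 10-second session of a phone resting on a trembling palm: gravity on
the z axis, a 5 Hz tremor oscillation, sensor noise, and realistic
sampling-time jitter around the nominal 50 Hz.
"""

import numpy as np

from tremorkit import TremorSimConfig, simulate_session

cfg = TremorSimConfig(tremor_freq_hz=5.0, tremor_amp=0.5, noise_sd=0.1, seed=1)
session = simulate_session(cfg)

dt = np.diff(session.t)
mag = session.magnitude()
print(f"samples:            {session.t.size}")
print(f"duration:           {session.duration_s:.2f} s")
print(f"inter-sample gap:   {dt.mean():.2f} ± {dt.std():.2f} ms "
      f"(nominal {1000 / cfg.nominal_rate_hz:.0f} ms)")
print(f"|a| mean:           {mag.mean():.3f} m/s^2  (gravity ~9.81)")
print(f"|a| fluctuation sd: {mag.std():.3f} m/s^2  (tremor + noise)")

# The mean magnitude sits at gravity; the sd reflects the 0.5 m/s^2
# tremor oscillation plus sensor noise. The jittered gaps mimic real
# smartphone timestamps, which is why resampling is needed downstream.
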