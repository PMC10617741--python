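"""Derived-variable formulas on trial-level inputs.

Computes the symmetry angle for a left/right torque pair, MAD% gait
variability over five steps, the Romberg ratio, and the rate of torque
development (RTD) from a simulated torque-time ramp.
"""

import numpy as np

import fallrisk as fr
from fallrisk import TorqueTrace

# inter-limb symmetry: 0% = perfect symmetry, 50% = one side zero
sa = fr.symmetry_angle(60.0, 40.0)
print(f"symmetry angle for torques 60 vs 40 Nm: {sa:.2f}%")

# gait variability: MAD of five step measurements as % of the median
steps = [10.0, 12.0, 11.0, 13.0, 14.0]
print(f"MAD% of steps {steps}: {fr.mad_percent(steps):.2f}%")

# visual contribution to balance
print(f"Romberg ratio (EC 2.0, EO 1.0 deg/s): {fr.romberg_ratio(2.0, 1.0):.2f}")

# RTD from a 2000 Hz torque trace: 0.5 s rest at 2 Nm, then a 120 Nm/s ramp
rate = 2000.0
rest = np.full(1000, 2.0)
ramp = 2.0 + 120.0 * np.arange(1500) / rate
trace = TorqueTrace(np.concatenate([rest, ramp]), rate=rate)
filtered = fr.butterworth_lowpass(trace, cutoff=150.0)
onset = fr.detect_onset(filtered, delta=4.0)
vals = fr.rtd(filtered)
print(f"contraction onset at sample {onset} "
      f"({onset / rate * 1000:.0f} ms into the trace)")
print("RTD over 0-50 / 0-100 / 0-200 ms:",
      ", ".join(f"{v:.1f}" for v in vals), "Nm/s")
# A linear ramp yields the ramp slope in every window.
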