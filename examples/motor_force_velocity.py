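"""Force-velocity relation of a single myosin arm.

Clamps a bound motor arm at fixed resisting loads and measures its mean
walking velocity along a 7-nm site lattice.  The calibrated catch-bond rate
model gives an unloaded velocity of ~140 nm/s and a stall force of ~5.7 pN;
the printed zero-crossing of the fitted line is the measured stall force.
"""
import numpy as np

from actomyo import force_velocity_curve, stall_force_estimate

loads = np.arange(0.0, 7.25, 0.5)
v = force_velocity_curve(loads, n_replicates=100, seed=3)
print(" load (pN)   velocity (nm/s)")
for f, vi in zip(loads, v):
    print(f"   {f:5.2f}      {vi:7.1f}")
stall = stall_force_estimate(loads, n_replicates=100, seed=3)
print(f"\nunloaded velocity: {v[0]:.1f} nm/s (set point 140)")
print(f"stall force (zero crossing): {stall:.2f} pN (set point 5.7)")
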