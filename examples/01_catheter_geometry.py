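"""Build the two-loop mapping catheter and inspect its bipolar channels.

The catheter has 20 electrodes on 5 branches; adjacent electrode pairs
form 10 bipolar channels, five on an inner loop (pair indices 1-9) and
five on an outer loop (11-19), with pair k+10 sharing the branch of
pair k.
"""

import numpy as np

import focimap as fm

layout = fm.build_pentaray_layout(center=(0, 0, 0), orientation=0.0, inner_radius=5.0, outer_radius=15.0)

print(f"electrodes: {len(layout.electrodes)}, bipolar channels: {len(fm.pair_channels(layout))}")
for chan in fm.pair_channels(layout):
    x, y, _ = chan.midpoint
    print(f"  pair {chan.pair_index:2d} ({chan.loop:5s} loop)  midpoint ({x:6.2f}, {y:6.2f}) mm")

# Rotating the device by a fifth of a turn maps each branch onto the next:
rotated = fm.build_pentaray_layout(orientation=2 * np.pi / 5)
shift = np.linalg.norm(rotated.pair_midpoints - layout.pair_midpoints[[1, 2, 3, 4, 0, 6, 7, 8, 9, 5]])
print(f"\n72-degree rotation = cyclic branch permutation (mismatch {shift:.1e} mm)")
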