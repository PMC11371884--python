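"""Build the hemisphere ray-direction set and inspect its geometry.

The 198 quasi-uniform unit vectors on the superior hemisphere play the role
of the vertices of a reference hemi-icosphere placed at the condyle
centroid: one joint-gap measurement is taken along each of them.
"""

import numpy as np

from condyseat import build_direction_set

ds = build_direction_set(198)
z = ds.directions[:, 2]
print(f"directions: {ds.n}")
print(f"max |norm - 1|: {np.abs(np.linalg.norm(ds.directions, axis=1) - 1).max():.2e}")
print(f"superior components: min {z.min():.4f}, mean {z.mean():.4f} (uniform hemisphere -> 0.5)")
print(f"first direction (the superior pole): {ds.directions[0]}")

# The mean superior component near 0.5 confirms quasi-uniform coverage of the
# hemisphere; the pole is included so n = 1 degenerates to a single superior ray.
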