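"""Measure the joint space of a synthetic condyle/fossa phantom by ray-casting.

A condyle sphere (r = 5 mm) sits 1 mm off-center inside a fossa shell
(inner r = 7 mm); the ray-caster should report direction-dependent gaps
that match the closed-form line-sphere solution to within one voxel
diagonal (0.4 mm voxels -> 0.69 mm).
"""

import numpy as np

from condyseat import PhantomSpec, analytic_gap, build_direction_set, extract_features, rasterize_phantom

spec = PhantomSpec(fossa_coverage_deg=180.0, displacement_mm=(0.0, 0.0, -1.0))
volume = rasterize_phantom(spec)
ds = build_direction_set(198)

features = extract_features(volume, ds, joint_id="phantom")
expected = np.array([analytic_gap(spec, u) for u in ds.directions])

print(f"volume shape {volume.shape}, spacing {volume.spacing} mm")
print(f"measured gaps: min {features.distances.min():.3f}, max {features.distances.max():.3f} mm")
print(f"imputed rays: {features.n_imputed} of {ds.n}")
print(f"max |measured - analytic|: {np.abs(features.distances - expected).max():.3f} mm")
print(f"one voxel diagonal: {0.4 * np.sqrt(3):.3f} mm")

# The condyle is displaced 1 mm inferior, so superior rays see a widened gap
# (3 mm at the pole) while near-horizontal rays see about 2 mm: the
# direction-resolved gap profile is exactly the signal the classifier uses.
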