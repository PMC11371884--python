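import numpy as np
import pytest

from condyseat import (
    LabelVolume,
    PhantomSpec,
    analytic_gap,
    build_direction_set,
    cast_ray,
    condyle_centroid,
    extract_features,
    impute,
    mirror_pair,
    rasterize_phantom,
)
from condyseat.raycast import brute_force_gap

from conftest import random_shell_spec

DIAG_04 = 0.4 * np.sqrt(3)


class TestCastRay:
    def test_concentric_gap_is_two_mm(self, concentric_volume):
        origin = condyle_centroid(concentric_volume)
        for d in ([0, 0, 1], [0.6, 0, 0.8], [0, -0.8, 0.6]):
            hit = cast_ray(concentric_volume, origin, np.array(d, dtype=float))
            assert hit.status == "ok"
            assert abs(hit.gap_mm - 2.0) < DIAG_04

    def test_hit_points_lie_on_the_ray(self, concentric_volume):
        origin = condyle_centroid(concentric_volume)
        d = np.array([0.6, 0.0, 0.8])
        hit = cast_ray(concentric_volume, origin, d)
        for p in (hit.condyle_exit, hit.fossa_entry):
            off = p - origin
            cross = np.linalg.norm(np.cross(off, d))
            assert cross < 1e-6
        assert abs(hit.gap_mm - np.linalg.norm(hit.fossa_entry - hit.condyle_exit)) < 1e-9

    def test_erased_octant_reports_no_fossa(self, concentric_volume):
        vox = concentric_volume.voxels.copy()
        h = vox.shape[0] // 2
        octant = vox[h:, h:, h:]
        octant[octant == 2] = 0
        vol = LabelVolume(vox, concentric_volume.spacing, concentric_volume.origin)
        origin = condyle_centroid(vol)
        hit = cast_ray(vol, origin, np.array([0.6, 0.6, 0.529150262212918]))
        assert hit.status == "no_fossa"
        hit2 = cast_ray(vol, origin, np.array([-0.6, -0.6, 0.529150262212918]))
        assert hit2.status == "ok"

    def test_origin_outside_grid_raises(self, concentric_volume):
        with pytest.raises(ValueError, match="outside"):
            cast_ray(concentric_volume, np.array([100.0, 0.0, 0.0]), np.array([0, 0, 1.0]))

    def test_zero_direction_raises(self, concentric_volume):
        origin = condyle_centroid(concentric_volume)
        with pytest.raises(ValueError, match="zero"):
            cast_ray(concentric_volume, origin, np.zeros(3))

    def test_displaced_sphere_matches_line_sphere_solution(self):
        rng = np.random.default_rng(42)
        spec = PhantomSpec(
            fossa_coverage_deg=180.0, displacement_mm=(0.5, -0.4, -0.8)
        )
        vol = rasterize_phantom(spec)
        origin = condyle_centroid(vol)
        for _ in range(50):
            u = rng.normal(size=3)
            u[2] = abs(u[2])
            u /= np.linalg.norm(u)
            hit = cast_ray(vol, origin, u)
            expected = analytic_gap(spec, u)
            assert hit.status == "ok"
            assert abs(hit.gap_mm - expected) < DIAG_04


class TestImpute:
    def test_no_missing_is_identity(self):
        d = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(impute(d, [True, True, True]), d)

    def test_midpoint_value(self):
        out = impute([1.0, 0.0, 3.0], [True, False, True], policy="midpoint")
        assert out[1] == 2.0

    def test_uniform_draws_bounded_with_correct_mean(self):
        d = np.zeros(10_002)
        ok = np.zeros(10_002, dtype=bool)
        d[0], d[1] = 1.0, 3.0
        ok[:2] = True
        out = impute(d, ok, policy="uniform", rng_seed=7)
        draws = out[2:]
        assert draws.min() >= 1.0 and draws.max() <= 3.0
        assert abs(draws.mean() - 2.0) < 0.05

    def test_uniform_is_seeded(self):
        a = impute([1.0, 0.0, 3.0], [True, False, True], "uniform", rng_seed=5)
        b = impute([1.0, 0.0, 3.0], [True, False, True], "uniform", rng_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_measured_rays_raise(self):
        with pytest.raises(ValueError, match="zero measured"):
            impute([1.0, 2.0], [False, False])


class TestExtractFeatures:
    def test_concentric_full_shell_all_gaps_two_mm(self, concentric_volume, ds198):
        fv = extract_features(concentric_volume, ds198, joint_id="c")
        assert fv.n_imputed == 0
        np.testing.assert_allclose(fv.distances, 2.0, atol=DIAG_04)

    def test_half_coverage_imputes_within_measured_range(self, ds198):
        # cap to ~half of the hemisphere solid angle: cos(polar) >= 0.5
        spec = PhantomSpec(fossa_coverage_deg=60.0)
        fv = extract_features(rasterize_phantom(spec), ds198, joint_id="h")
        frac = fv.n_imputed / ds198.n
        assert 0.35 < frac < 0.65
        measured = fv.distances[~fv.imputed]
        assert np.all(fv.distances[fv.imputed] >= measured.min())
        assert np.all(fv.distances[fv.imputed] <= measured.max())

    def test_deterministic_for_fixed_seed(self, capped_volume, ds198):
        a = extract_features(capped_volume, ds198, imputation="uniform", rng_seed=3)
        b = extract_features(capped_volume, ds198, imputation="uniform", rng_seed=3)
        np.testing.assert_array_equal(a.distances, b.distances)
        np.testing.assert_array_equal(a.imputed, b.imputed)

    def test_no_fossa_coverage_raises(self, ds198):
        spec = PhantomSpec()
        vol = rasterize_phantom(spec)
        vox = vol.voxels.copy()
        vox[vox == 2] = 0
        empty_fossa = LabelVolume(vox, vol.spacing, vol.origin)
        with pytest.raises(ValueError, match="no fossa coverage"):
            extract_features(empty_fossa, ds198)

    def test_centroid_outside_condyle_raises(self, ds198):
        # two disjoint condyle blobs whose mean falls in background
        vox = np.zeros((40, 40, 40), dtype=int)
        vox[2:6, 18:22, 18:22] = 1
        vox[34:38, 18:22, 18:22] = 1
        vox[10:30, 10:30, 30:34] = 2
        vol = LabelVolume(vox, np.full(3, 0.4), np.zeros(3))
        with pytest.raises(ValueError, match="centroid not inside condyle"):
            extract_features(vol, ds198)


class TestTraversalProperties:
    def test_brute_force_oracle_equivalence(self, ds198):
        rng = np.random.default_rng(9)
        spec = random_shell_spec(rng, full_shell=False)
        vol = rasterize_phantom(spec)
        origin = condyle_centroid(vol)
        diag = float(np.linalg.norm(vol.spacing))
        for u in ds198.directions[::7]:
            hit = cast_ray(vol, origin, u)
            bf = brute_force_gap(vol, origin, u)
            if hit.status == "ok":
                assert bf is not None
                assert abs(hit.gap_mm - bf) < diag
            else:
                assert bf is None

    def test_translation_invariance(self, ds198, concentric_spec):
        vol = rasterize_phantom(concentric_spec)
        shift = np.array([13.0, -4.5, 2.25])
        shifted = LabelVolume(vol.voxels.copy(), vol.spacing, vol.origin + shift)
        a = extract_features(vol, ds198, joint_id="a")
        b = extract_features(shifted, ds198, joint_id="b")
        np.testing.assert_array_equal(a.distances, b.distances)

    def test_voxel_size_independence(self, ds198):
        spec_04 = PhantomSpec(fossa_coverage_deg=180.0, displacement_mm=(0.3, -0.2, -0.5))
        spec_02 = PhantomSpec(
            fossa_coverage_deg=180.0, displacement_mm=(0.3, -0.2, -0.5), spacing_mm=0.2
        )
        f_04 = extract_features(rasterize_phantom(spec_04), ds198)
        f_02 = extract_features(rasterize_phantom(spec_02), ds198)
        assert np.abs(f_04.distances - f_02.distances).max() < DIAG_04

    def test_mirror_symmetry_exact(self, ds198):
        spec = PhantomSpec(fossa_coverage_deg=180.0, displacement_mm=(0.9, 0.4, -0.6))
        vol = rasterize_phantom(spec)
        mirrored = mirror_pair(vol)
        a = extract_features(vol, ds198, joint_id="a")
        b = extract_features(mirrored, ds198.mirrored(), joint_id="b")
        np.testing.assert_array_equal(a.distances, b.distances)
        np.testing.assert_array_equal(a.imputed, b.imputed)
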