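"""Tests of the synthetic LCN generator, rasterizer and renderer."""

import math

import numpy as np
import pytest

from lcnquant import GenerationParams, ImagingParams, VoxelGrid
from lcnquant.phantom import (Canaliculus, GroundTruth, PackingError,
                              generate_network, rasterize_truth, render_image,
                              save_truth, load_truth, shape_for)


class TestGenerationParams:
    def test_length_budget_closed_form(self):
        # 1% of 64x64x12 um^3 as 200 nm tubes: L = 0.01*49152/(pi*0.01)
        p = GenerationParams(volume_um=(12, 64, 64), canal_fraction_pct=1.0,
                             canal_radius_um=0.1)
        assert p.target_length_um == pytest.approx(1.5646e4, rel=1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"canal_fraction_pct": 0.0},
        {"canal_fraction_pct": 12.0},
        {"canal_radius_um": -0.1},
        {"spacing_um": (0.3, 0.0, 0.2)},
        {"lacuna_semiaxes_um": ((0.05, 0.1), (1, 2), (1, 2))},
        {"orientation_regime": "spiral"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenerationParams(**kwargs)


class TestGenerateNetwork:
    def test_zero_density_gives_empty_network(self):
        gt = generate_network(GenerationParams(lacuna_density_mm3=0.0))
        assert gt.lacunae == [] and gt.canaliculi == []
        assert gt.total_length_um == 0.0

    def test_volume_too_small_for_one_lacuna(self):
        with pytest.raises(ValueError, match="too small"):
            generate_network(GenerationParams(
                volume_um=(12, 24, 24), lacuna_density_mm3=7e4))

    def test_deterministic_under_seed(self, small_params):
        a = generate_network(small_params)
        b = generate_network(small_params)
        assert a.summary() == b.summary()
        assert len(a.canaliculi) == len(b.canaliculi)
        for ca, cb in zip(a.canaliculi, b.canaliculi):
            np.testing.assert_array_equal(ca.points_um, cb.points_um)

    def test_length_budget_met_within_5pct(self, small_phantom):
        gt = small_phantom[4]
        lt = gt.params.target_length_um
        assert abs(gt.total_length_um - lt) / lt <= 0.05

    def test_hard_core_lacuna_placement(self):
        p = GenerationParams(volume_um=(12, 90, 90), lacuna_density_mm3=7e4, seed=3)
        gt = generate_network(p)
        assert len(gt.lacunae) == round(7e4 * 12 * 90 * 90 * 1e-9)
        for i, a in enumerate(gt.lacunae):
            for b in gt.lacunae[i + 1:]:
                d = np.linalg.norm(a.center_um - b.center_um)
                assert d > a.max_semiaxis_um + b.max_semiaxis_um

    def test_infeasible_packing_raises(self):
        p = GenerationParams(volume_um=(12, 22, 22), lacuna_density_mm3=2e6, seed=0)
        with pytest.raises(PackingError):
            generate_network(p)

    def test_canaliculi_start_on_lacuna_surfaces(self, small_phantom):
        gt = small_phantom[4]
        # every root path starts within a small tolerance of some lacuna surface
        starts = [c.points_um[0] for c in gt.canaliculi]
        on_surface = sum(
            any(e.contains(s[None], margin_um=0.05)[0] for e in gt.lacunae)
            for s in starts
        )
        assert on_surface >= 1  # spawned side branches start mid-tissue


class TestRasterizeTruth:
    def _params(self, volume, spacing=(0.3, 0.2, 0.2)):
        return GenerationParams(volume_um=volume, spacing_um=spacing,
                                lacuna_density_mm3=0.0)

    def test_single_axial_tube(self):
        # straight tube along z through voxel centers: 1-voxel-wide line
        p = self._params((12.6, 4.2, 4.2))
        pts = np.array([[1.0, 2.1, 2.1], [11.0, 2.1, 2.1]])
        gt = GroundTruth([], [Canaliculus(pts, 0.1)], np.empty((0, 3)), p, 0)
        canal, lacuna, skel = rasterize_truth(gt)
        assert not lacuna.values.any()
        per_slice = canal.values.sum(axis=(1, 2))
        assert set(per_slice.tolist()) <= {0, 1}
        assert canal.values.sum() >= 30  # ~10 um / 0.3 um slices
        assert skel.n_branches == 1
        assert skel.n_endpoints == 2
        assert skel.n_junctions == 0
        assert skel.total_length_um == pytest.approx(10.0, abs=0.5)

    def test_ellipsoid_volume_within_10pct(self):
        from lcnquant.phantom import Ellipsoid

        p = self._params((8, 8, 8), spacing=(0.2, 0.2, 0.2))
        e = Ellipsoid(np.array([4.0, 4.0, 4.0]), np.array([1.0, 1.0, 2.0]), 30.0)
        gt = GroundTruth([e], [], np.empty((0, 3)), p, 0)
        _, lacuna, _ = rasterize_truth(gt)
        analytic = 4 / 3 * math.pi * 2 * 1 * 1
        measured = lacuna.values.sum() * 0.2 ** 3
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_empty_truth_gives_zero_masks(self):
        p = self._params((6, 6, 6))
        gt = GroundTruth([], [], np.empty((0, 3)), p, 0)
        canal, lacuna, skel = rasterize_truth(gt)
        assert not canal.values.any() and not lacuna.values.any()
        assert skel.n_branches == 0

    def test_truth_skeleton_lengths_match_polylines(self, small_phantom):
        gt = small_phantom[4]
        skel = small_phantom[3]
        assert skel.total_length_um == pytest.approx(gt.total_length_um, rel=1e-9)

    def test_shape_mismatch_rejected(self, small_phantom):
        gt = small_phantom[4]
        with pytest.raises(ValueError, match="exceeds"):
            rasterize_truth(gt, spacing=(0.3, 0.2, 0.2), shape=(4, 4, 4))

    def test_density_conservation(self, small_phantom):
        # voxelized canal fraction within 25% of the target at 200 nm sampling
        canal, gt = small_phantom[1], small_phantom[4]
        frac = 100.0 * canal.values.mean()
        assert frac == pytest.approx(gt.params.canal_fraction_pct, rel=0.25)

    def test_lacuna_component_count_matches(self):
        from scipy import ndimage as ndi

        p = GenerationParams(volume_um=(12, 90, 90), lacuna_density_mm3=7e4, seed=3)
        gt = generate_network(p)
        _, lacuna, _ = rasterize_truth(gt)
        _, n = ndi.label(lacuna.values, structure=np.ones((3, 3, 3)))
        assert n == len(gt.lacunae)


class TestRenderImage:
    def _grids(self, shape=(10, 32, 32)):
        z = np.zeros(shape, dtype=bool)
        return VoxelGrid(z.copy()), VoxelGrid(z.copy())

    def test_zero_everything_renders_exact_zero(self):
        canal, lacuna = self._grids()
        ip = ImagingParams(background_mean=0, background_std=0,
                           foreground_amplitude=0, photon_scale=0)
        img = render_image(canal, lacuna, ip)
        assert np.all(img.values == 0)

    def test_geometry_mismatch_rejected(self):
        canal, _ = self._grids()
        _, lacuna = self._grids(shape=(10, 16, 16))
        with pytest.raises(ValueError, match="geometry"):
            render_image(canal, lacuna, ImagingParams())

    def test_point_source_lateral_fwhm(self):
        canal, lacuna = self._grids(shape=(21, 41, 41))
        canal.values[10, 20, 20] = True
        ip = ImagingParams(background_mean=0, background_std=0,
                           foreground_amplitude=100, photon_scale=0)
        img = render_image(canal, lacuna, ip)
        profile = img.values[10, 20, :]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - 1 + (half - profile[lo - 1]) / (profile[lo] - profile[lo - 1])
        f_hi = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        fwhm_um = (f_hi - f_lo) * img.spacing[2]
        assert fwhm_um == pytest.approx(0.43, rel=0.15)

    def test_render_deterministic(self, small_phantom, small_params):
        from lcnquant.phantom import simulate

        image2 = simulate(small_params, ImagingParams(seed=11))[0]
        np.testing.assert_array_equal(small_phantom[0].values, image2.values)


def test_truth_roundtrip(tmp_path, small_phantom):
    gt = small_phantom[4]
    save_truth(tmp_path / "truth.json", gt)
    back = load_truth(tmp_path / "truth.json")
    assert len(back.lacunae) == len(gt.lacunae)
    assert len(back.canaliculi) == len(gt.canaliculi)
    assert back.total_length_um == pytest.approx(gt.total_length_um, abs=1e-2)
    assert shape_for(back.params) == shape_for(gt.params)
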