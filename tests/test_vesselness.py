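"""Tests of the 2D vesselness filter and hysteresis segmentation."""

import numpy as np
import pytest

from lcnquant import (HysteresisParams, VesselnessParams, VoxelGrid, frangi_2d,
                      frangi_stack, hessian_eigen_2d, hysteresis_threshold)


def _ridge(n=64, sigma=2.0, axis=0):
    """Analytic 1D Gaussian ridge image."""
    x = np.arange(n) - n // 2
    profile = np.exp(-x ** 2 / (2 * sigma ** 2))
    img = np.tile(profile, (n, 1))
    return img if axis == 0 else img.T


def _blob(n=64, sigma=2.0):
    x = np.arange(n) - n // 2
    g = np.exp(-x ** 2 / (2 * sigma ** 2))
    return np.outer(g, g)


class TestHessianEigen:
    def test_constant_slice_zero_eigenvalues(self):
        lam1, lam2 = hessian_eigen_2d(np.full((32, 32), 3.7))
        assert np.allclose(lam1, 0) and np.allclose(lam2, 0)

    def test_eigenvalue_ordering_by_magnitude(self, rng):
        img = rng.normal(size=(40, 40))
        lam1, lam2 = hessian_eigen_2d(img, sigma_px=2.0)
        assert np.all(np.abs(lam1) <= np.abs(lam2) + 1e-12)

    def test_ridge_centerline_eigenvalues(self):
        # vertical ridge: strong negative curvature across, ~none along
        img = _ridge(sigma=2.0, axis=0)
        lam1, lam2 = hessian_eigen_2d(img, sigma_px=1.0)
        center = np.s_[20:44, 32]
        assert np.all(lam2[center] < 0)
        assert np.all(np.abs(lam1[center]) < 0.2 * np.abs(lam2[center]))

    def test_finite_difference_oracle(self):
        # compare against direct second differences of the Gaussian-smoothed image
        from scipy import ndimage as ndi

        rng = np.random.default_rng(7)
        img = ndi.gaussian_filter(rng.normal(size=(48, 48)), 3.0)
        sigma = 1.5
        lam1, lam2 = hessian_eigen_2d(img, sigma_px=sigma)
        smooth = ndi.gaussian_filter(img, sigma, mode="reflect")
        hyy = np.gradient(np.gradient(smooth, axis=0), axis=0)
        hxx = np.gradient(np.gradient(smooth, axis=1), axis=1)
        hxy = np.gradient(np.gradient(smooth, axis=0), axis=1)
        interior = np.s_[8:-8, 8:-8]
        tr_direct = (hxx + hyy)[interior]
        tr_ours = (lam1 + lam2)[interior]
        assert np.corrcoef(tr_direct.ravel(), tr_ours.ravel())[0, 1] > 0.99
        det_direct = (hxx * hyy - hxy ** 2)[interior]
        det_ours = (lam1 * lam2)[interior]
        assert np.corrcoef(det_direct.ravel(), det_ours.ravel())[0, 1] > 0.98

    def test_rotational_equivariance_90deg(self, rng):
        from scipy import ndimage as ndi

        img = ndi.gaussian_filter(rng.normal(size=(40, 40)), 2.0)
        lam1, lam2 = hessian_eigen_2d(img)
        lam1r, lam2r = hessian_eigen_2d(np.rot90(img))
        np.testing.assert_allclose(lam1r, np.rot90(lam1), atol=1e-8)
        np.testing.assert_allclose(lam2r, np.rot90(lam2), atol=1e-8)

    def test_nonfinite_input_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            hessian_eigen_2d(img)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            hessian_eigen_2d(np.zeros((3, 3)))


class TestFrangi2d:
    def test_constant_slice_zero_response(self):
        assert np.all(frangi_2d(np.full((32, 32), 5.0)) == 0)

    def test_response_bounded_unit_interval(self, rng):
        for _ in range(5):
            img = rng.normal(size=(32, 32))
            v = frangi_2d(img)
            assert np.all(v >= 0) and np.all(v <= 1)

    def test_ridge_beats_blob(self):
        ridge, blob = _ridge(), _blob()
        vr = frangi_2d(ridge, VesselnessParams(c=0.05))
        vb = frangi_2d(blob, VesselnessParams(c=0.05))
        assert vr[32, 32] > vb[32, 32]

    def test_dark_tube_ignored_with_bright_polarity(self):
        v = frangi_2d(1.0 - _ridge())
        assert v[32, 32] == 0.0

    def test_agreement_with_skimage_reference(self):
        # independent oracle: scikit-image's implementation of the same filter
        from skimage.filters import frangi as sk_frangi

        img = _ridge(sigma=1.5) + 0.1 * np.random.default_rng(0).normal(size=(64, 64))
        ours = frangi_2d(img, VesselnessParams(sigma_px=1.0, beta=0.5, c=0.06))
        ref = sk_frangi(img, sigmas=[1.0], beta=0.5, gamma=0.06, black_ridges=False)
        mask = ref + ours > 1e-3
        assert np.corrcoef(ours[mask], ref[mask])[0, 1] > 0.95


class TestFrangiStack:
    def test_single_slice_equals_2d(self, rng):
        img = rng.normal(size=(24, 24))
        stack = VoxelGrid(img[None])
        np.testing.assert_array_equal(frangi_stack(stack).values[0], frangi_2d(img))

    def test_identical_slices_identical_responses(self, rng):
        img = rng.normal(size=(24, 24))
        stack = VoxelGrid(np.stack([img] * 4))
        out = frangi_stack(stack).values
        for z in range(1, 4):
            np.testing.assert_array_equal(out[z], out[0])

    def test_canal_voxels_respond_more_than_background(self, small_phantom):
        image, canal, lacuna = small_phantom[0], small_phantom[1], small_phantom[2]
        resp = frangi_stack(image).values
        on_tube = canal.values & ~lacuna.values
        off = ~(canal.values | lacuna.values)
        assert resp[on_tube].mean() > 3 * resp[off].mean()


def _brute_force_hysteresis(values, t_low, t_high):
    """Independent oracle: BFS flood fill from high voxels over the low mask."""
    from collections import deque

    low = values >= t_low
    out = np.zeros_like(low)
    seeds = np.argwhere(values >= t_high)
    queue = deque(map(tuple, seeds))
    for s in queue:
        out[s] = low[s]
    while queue:
        z, y, x = queue.popleft()
        if not out[z, y, x]:
            continue
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    q = (z + dz, y + dy, x + dx)
                    if all(0 <= q[i] < values.shape[i] for i in range(3)):
                        if low[q] and not out[q]:
                            out[q] = True
                            queue.append(q)
    return out


class TestHysteresis:
    def test_equal_thresholds_reduce_to_simple_threshold(self, rng):
        vals = rng.random((6, 10, 10))
        grid = VoxelGrid(vals)
        hp = HysteresisParams(t_low=0.6, t_high=0.6)
        np.testing.assert_array_equal(hysteresis_threshold(grid, hp).values, vals >= 0.6)

    def test_all_below_low_gives_empty_mask(self):
        grid = VoxelGrid(np.full((4, 8, 8), 0.1))
        hp = HysteresisParams(t_low=0.4, t_high=0.8)
        assert not hysteresis_threshold(grid, hp).values.any()

    def test_1d_chain_linking(self):
        # kept: seed 0.9 plus linked 0.5s; rejected: 0.5 isolated beyond 0.1
        vals = np.array([0.9, 0.5, 0.5, 0.1, 0.5])[None, None, :]
        hp = HysteresisParams(t_low=0.4, t_high=0.8)
        out = hysteresis_threshold(VoxelGrid(vals), hp).values[0, 0]
        np.testing.assert_array_equal(out, [True, True, True, False, False])

    def test_monotonicity_in_thresholds(self, rng):
        vals = rng.random((5, 12, 12))
        grid = VoxelGrid(vals)
        base = hysteresis_threshold(grid, HysteresisParams(t_low=0.3, t_high=0.7)).values
        for lo, hi in [(0.4, 0.7), (0.3, 0.8), (0.45, 0.85)]:
            tighter = hysteresis_threshold(grid, HysteresisParams(t_low=lo, t_high=hi)).values
            assert not (tighter & ~base).any()

    def test_idempotent_on_binary_fields(self, rng):
        vals = (rng.random((4, 9, 9)) > 0.6).astype(float)
        hp = HysteresisParams(t_low=0.5, t_high=0.5)
        np.testing.assert_array_equal(
            hysteresis_threshold(VoxelGrid(vals), hp).values, vals.astype(bool))

    def test_matches_brute_force_oracle_on_small_grids(self, rng):
        for _ in range(10):
            vals = rng.random((5, 10, 10))
            lo, hi = sorted(rng.uniform(0.2, 0.9, size=2))
            ours = hysteresis_threshold(VoxelGrid(vals),
                                        HysteresisParams(t_low=lo, t_high=hi)).values
            np.testing.assert_array_equal(ours, _brute_force_hysteresis(vals, lo, hi))

    def test_2d_connectivity_does_not_link_across_slices(self):
        vals = np.zeros((2, 3, 3))
        vals[0, 1, 1] = 1.0   # seed in slice 0
        vals[1, 1, 1] = 0.5   # weak voxel directly above
        hp2 = HysteresisParams(t_low=0.4, t_high=0.9, connectivity="2d")
        hp3 = HysteresisParams(t_low=0.4, t_high=0.9, connectivity="3d")
        assert not hysteresis_threshold(VoxelGrid(vals), hp2).values[1, 1, 1]
        assert hysteresis_threshold(VoxelGrid(vals), hp3).values[1, 1, 1]
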