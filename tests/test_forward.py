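"""Born weights, depth conversion matrices, expected images, forward projection."""

import numpy as np
import pytest

from fpirestore import (
    BlurryImage,
    VoxelGrid,
    YieldMap,
    add_noise,
    depth_conversion_matrix,
    expected_image_from_yield,
    green_slab,
    simulate_blurry_image,
    voxel_weight,
)


def brute_force_weight(m, n, i, setup):
    """Independent evaluation of C_{n,i}^{(m)} from the two factors."""
    grid = setup.grid
    iy, iz = grid.pixel_multi_index(n)
    node = grid.node_position(i, int(iy), int(iz))
    g_em = green_slab(
        node,
        grid.pixel_position(m),
        setup.optics,
        setup.slab,
        tol=setup.tol,
        rho_min=setup.rho_min,
    )
    phi = setup.source.strength * green_slab(
        node,
        np.asarray(setup.source.position),
        setup.optics,
        setup.slab,
        tol=setup.tol,
        rho_min=setup.rho_min,
    )
    return g_em * phi


def brute_force_blurry(f, setup):
    """Direct triple sum over all voxels for every pixel."""
    grid = setup.grid
    b = np.zeros(grid.npix)
    for m in range(grid.npix):
        for n in range(grid.npix):
            iy, iz = grid.pixel_multi_index(n)
            for i in range(grid.counts[0]):
                b[m] += brute_force_weight(m, n, i, setup) * f.values[
                    i, int(iy), int(iz)
                ]
    return grid.delta_v * b


class TestVoxelWeight:
    def test_matches_brute_force_on_toy_grid(self, toy_setup):
        for m, n, i in [(0, 0, 0), (4, 4, 1), (8, 2, 2), (3, 7, 1)]:
            assert voxel_weight(m, n, i, toy_setup) == pytest.approx(
                brute_force_weight(m, n, i, toy_setup), rel=1e-12
            )

    def test_out_of_range_rejected(self, toy_setup):
        with pytest.raises(IndexError):
            voxel_weight(9, 0, 0, toy_setup)
        with pytest.raises(IndexError):
            voxel_weight(0, 0, 3, toy_setup)

    def test_mirror_symmetry_about_source(self, phantom):
        # expected pixel at the source's lateral position: weights for two
        # blurry pixels mirrored about that position are equal
        setup = phantom["setup"]
        grid = setup.grid
        c = grid.counts[1] // 2  # source enters at the lateral center
        n = grid.pixel_index(c, c)
        m_lo = grid.pixel_index(c - 4, c)
        m_hi = grid.pixel_index(c + 4, c)
        for i in (5, 20):
            assert voxel_weight(m_lo, n, i, setup) == pytest.approx(
                voxel_weight(m_hi, n, i, setup), rel=1e-10
            )

    def test_depth_profile_peaks_between_boundaries(self, phantom):
        # for the central pixel pair the weight along depth is maximal at an
        # interior depth balancing the source and detector distances
        setup = phantom["setup"]
        c = setup.grid.counts[1] // 2
        n = m = setup.grid.pixel_index(c, c)
        dcm = depth_conversion_matrix(n, setup)
        profile = dcm.entries[m, :]
        k = int(np.argmax(profile))
        assert 0 < k < setup.grid.counts[0] - 1
        brute = [brute_force_weight(m, n, i, setup) for i in range(len(profile))]
        assert k == int(np.argmax(brute))


class TestDepthConversionMatrix:
    def test_matches_brute_force_on_toy_grid(self, toy_setup):
        n = 4
        dcm = depth_conversion_matrix(n, toy_setup)
        grid = toy_setup.grid
        assert dcm.entries.shape == (grid.npix, grid.counts[0])
        for m in range(grid.npix):
            for i in range(grid.counts[0]):
                assert dcm.entries[m, i] == pytest.approx(
                    brute_force_weight(m, n, i, toy_setup), rel=1e-12
                )

    def test_positive_with_positive_row_sums(self, phantom):
        dcm = depth_conversion_matrix(17, phantom["setup"])
        assert np.all(dcm.entries > 0)
        assert np.all(dcm.row_sums > 0)

    def test_reference_grid_shape(self):
        # 3 cm cube at 0.05 cm spacing: 61 nodes per axis, 3721 pixels,
        # so each depth conversion matrix is 3721 x 61
        grid = VoxelGrid.from_extent((3.0, 3.0, 3.0), 0.05)
        assert grid.counts == (61, 61, 61)
        assert (grid.npix, grid.counts[0]) == (3721, 61)


class TestExpectedImage:
    def test_constant_depth_yield_reproduced_for_any_reference(self, toy_setup):
        grid = toy_setup.grid
        lateral = np.random.default_rng(0).uniform(1.0, 2.0, grid.counts[1:])
        f = YieldMap(np.broadcast_to(lateral, grid.counts).copy(), grid)
        for m in (0, 5):
            fimg = expected_image_from_yield(f, m, toy_setup)
            np.testing.assert_allclose(fimg.pixels, lateral, rtol=1e-12)

    def test_convex_combination_bounds(self, toy_setup):
        grid = toy_setup.grid
        values = np.random.default_rng(1).uniform(0.0, 3.0, grid.counts)
        f = YieldMap(values, grid)
        fimg = expected_image_from_yield(f, 2, toy_setup)
        assert np.all(fimg.pixels <= values.max(axis=0) + 1e-12)
        assert np.all(fimg.pixels >= values.min(axis=0) - 1e-12)

    def test_single_depth_slab_formula(self, toy_setup):
        grid = toy_setup.grid
        i0, amp = 1, 2.5
        values = np.zeros(grid.counts)
        values[i0] = amp
        f = YieldMap(values, grid)
        m = 3
        fimg = expected_image_from_yield(f, m, toy_setup)
        dcm_cols = {
            n: depth_conversion_matrix(n, toy_setup).entries[m, :]
            for n in range(grid.npix)
        }
        for n in range(grid.npix):
            iy, iz = grid.pixel_multi_index(n)
            w = dcm_cols[n]
            assert fimg.pixels[int(iy), int(iz)] == pytest.approx(
                amp * w[i0] / w.sum(), rel=1e-10
            )

    def test_nonuniqueness_across_reference_pixels(self, phantom):
        # yield varying along depth: expected images anchored at different
        # blurry pixels disagree in where their maximum sits; depth-constant
        # yield removes the dependence entirely
        setup = phantom["setup"]
        grid = setup.grid
        values = np.zeros(grid.counts)
        # two shallow voxels near opposite detector corners: the weights of
        # a nearby reference pixel favour the shallow depth much more
        values[2, 2, 2] = 1.0
        values[2, 28, 28] = 1.0
        f = YieldMap(values, grid)
        corner_a, corner_b = 0, grid.npix - 1
        img_a = expected_image_from_yield(f, corner_a, setup).pixels
        img_b = expected_image_from_yield(f, corner_b, setup).pixels
        assert np.unravel_index(np.argmax(img_a), img_a.shape) != np.unravel_index(
            np.argmax(img_b), img_b.shape
        )


class TestSimulateBlurryImage:
    def test_zero_yield_gives_zero_image(self, toy_setup):
        f = YieldMap(np.zeros(toy_setup.grid.counts), toy_setup.grid)
        assert np.all(simulate_blurry_image(f, toy_setup).pixels == 0)

    def test_superposition(self, toy_setup):
        rng = np.random.default_rng(2)
        grid = toy_setup.grid
        f1 = YieldMap(rng.uniform(0, 1, grid.counts), grid)
        f2 = YieldMap(rng.uniform(0, 1, grid.counts), grid)
        both = YieldMap(f1.values + f2.values, grid)
        np.testing.assert_allclose(
            simulate_blurry_image(both, toy_setup).pixels,
            simulate_blurry_image(f1, toy_setup).pixels
            + simulate_blurry_image(f2, toy_setup).pixels,
            rtol=1e-12,
        )

    def test_single_voxel_two_factor_product(self, toy_setup):
        grid = toy_setup.grid
        values = np.zeros(grid.counts)
        values[1, 0, 2] = 3.0
        f = YieldMap(values, grid)
        b = simulate_blurry_image(f, toy_setup)
        n = grid.pixel_index(0, 2)
        for m in range(grid.npix):
            expected = grid.delta_v * 3.0 * brute_force_weight(m, n, 1, toy_setup)
            assert b.vector[m] == pytest.approx(expected, rel=1e-12)

    def test_triple_sum_and_expected_image_routes_agree(self, toy_setup):
        # route A: direct voxel triple sum; route B: sparse forward
        # projection; route C: Delta V * sum_n C_n^(m) F_n^(m)
        grid = toy_setup.grid
        f = YieldMap(np.random.default_rng(3).uniform(0, 1, grid.counts), grid)
        route_b = simulate_blurry_image(f, toy_setup).vector
        route_a = brute_force_blurry(f, toy_setup)
        np.testing.assert_allclose(route_b, route_a, rtol=1e-10)
        route_c = np.empty(grid.npix)
        for m in range(grid.npix):
            fimg = expected_image_from_yield(f, m, toy_setup)
            c_m = np.array(
                [
                    depth_conversion_matrix(n, toy_setup).entries[m, :].sum()
                    for n in range(grid.npix)
                ]
            )
            route_c[m] = grid.delta_v * np.dot(c_m, fimg.vector)
        np.testing.assert_allclose(route_b, route_c, rtol=1e-10)

    def test_negative_yield_rejected(self, toy_setup):
        grid = toy_setup.grid
        with pytest.raises(ValueError):
            YieldMap(-np.ones(grid.counts), grid)


class TestAddNoise:
    def _image(self, npix_side=101):
        grid = VoxelGrid(spacing=(1.0, 0.05, 0.05), counts=(2, npix_side, npix_side))
        rng = np.random.default_rng(4)
        return BlurryImage(rng.uniform(0.5, 1.0, (npix_side, npix_side)), grid)

    def test_zero_level_is_identity(self):
        b = self._image(11)
        for model in ("gaussian", "poisson"):
            np.testing.assert_array_equal(
                add_noise(b, model, level=0.0, seed=1).pixels, b.pixels
            )

    def test_seed_determinism(self):
        b = self._image(11)
        n1 = add_noise(b, "gaussian", 0.05, seed=42).pixels
        n2 = add_noise(b, "gaussian", 0.05, seed=42).pixels
        np.testing.assert_array_equal(n1, n2)
        n3 = add_noise(b, "poisson", 1e4, seed=9).pixels
        n4 = add_noise(b, "poisson", 1e4, seed=9).pixels
        np.testing.assert_array_equal(n3, n4)

    def test_gaussian_sample_sigma(self):
        # 101 x 101 pixels: sample sigma of the added noise within 5% of
        # level * max(B) by the law of large numbers
        b = self._image(101)
        level = 0.01
        noisy = add_noise(b, "gaussian", level, seed=0)
        sigma = np.std(noisy.pixels - b.pixels)
        assert sigma == pytest.approx(level * b.pixels.max(), rel=0.05)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            add_noise(self._image(11), "gaussian", -0.1, seed=0)
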