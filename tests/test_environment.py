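"""Nutrient lattice: diffusion, inter-layer flow, gradients, refeeds."""

import numpy as np
import pytest

from colonysim.environment import (
    NutrientLayers,
    PlateGeometry,
    RefeedEvent,
    apply_refeed,
    diffuse_layer,
    init_gradient_plate,
    interlayer_flow,
)


def brute_force_gaussian(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Independent oracle: explicit truncated-Gaussian convolution with
    symmetric (reflective) padding, normalised to sum 1."""
    radius = int(4.0 * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    kernel1d = np.exp(-(offsets**2) / (2 * sigma**2))
    kernel1d /= kernel1d.sum()
    padded = np.pad(grid, radius, mode="symmetric")
    out = np.zeros_like(grid, dtype=float)
    n_rows, n_cols = grid.shape
    for i in range(n_rows):
        for j in range(n_cols):
            block = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            out[i, j] = float(np.einsum("i,ij,j->", kernel1d, block, kernel1d))
    return out


class TestDiffuseLayer:
    def test_constant_field_is_fixed_point(self, rect_geometry):
        grid = np.full((40, 50), 3.7)
        out = diffuse_layer(grid, sigma=2.0)
        np.testing.assert_allclose(out, grid, atol=1e-12)

    def test_zero_sigma_is_identity(self, rng):
        grid = rng.random((20, 20))
        np.testing.assert_array_equal(diffuse_layer(grid, 0.0), grid)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            diffuse_layer(np.ones((5, 5)), -1.0)

    def test_point_mass_conserved_and_matches_convolution_oracle(self):
        grid = np.zeros((11, 11))
        grid[5, 5] = 100.0
        out = diffuse_layer(grid, sigma=1.0)
        assert abs(out.sum() - 100.0) <= 1e-9
        expected = brute_force_gaussian(grid, 1.0)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.5])
    def test_mass_conserved_on_random_fields(self, rng, sigma):
        grid = rng.random((33, 47)) * 10
        out = diffuse_layer(grid, sigma)
        assert abs(out.sum() - grid.sum()) / grid.sum() <= 1e-9

    def test_masked_diffusion_conserves_and_respects_mask(self, rng, circle_geometry):
        mask = circle_geometry.mask
        grid = np.where(mask, rng.random(mask.shape) * 5, 0.0)
        out = diffuse_layer(grid, 1.5, mask)
        assert abs(out.sum() - grid.sum()) / grid.sum() <= 1e-9
        assert (out[~mask] == 0).all()
        assert (out >= 0).all()


class TestInterlayerFlow:
    def test_equilibrium_ratio_is_fixed_point(self):
        top, deep = interlayer_flow(np.array([1.0]), np.array([2.0]), 1.0, 2.0, 0.7)
        assert top[0] == pytest.approx(1.0) and deep[0] == pytest.approx(2.0)

    def test_direct_evaluation_of_flow_update(self):
        # delta = (4/2 - 0) * 1/2 = 1
        top, deep = interlayer_flow(np.array([0.0]), np.array([4.0]), 1.0, 2.0, 1.0)
        assert top[0] == pytest.approx(1.0)
        assert deep[0] == pytest.approx(3.0)

    def test_pair_sum_exactly_conserved(self, rng):
        top = rng.random((30, 30)) * 9
        deep = rng.random((30, 30)) * 9
        new_top, new_deep = interlayer_flow(top, deep, 2.0, 3.0, 0.8)
        np.testing.assert_allclose(new_top + new_deep, top + deep, rtol=1e-15, atol=0)

    def test_idempotent_at_equilibrium(self, rng):
        top = rng.random((10, 10)) + 0.5
        deep = top * 3.0  # equilibrium for init ratio 3
        t1, d1 = interlayer_flow(top, deep, 1.0, 3.0, 0.9)
        t2, d2 = interlayer_flow(t1, d1, 1.0, 3.0, 0.9)
        np.testing.assert_allclose(t2, t1, atol=1e-12)
        np.testing.assert_allclose(d2, d1, atol=1e-12)

    @pytest.mark.parametrize("flowrate", [0.3, 1.0])
    def test_converges_to_init_ratio(self, rng, flowrate):
        top = rng.random(50) * 4
        deep = rng.random(50) * 4
        for _ in range(200):
            top, deep = interlayer_flow(top, deep, 1.0, 2.0, flowrate)
        np.testing.assert_allclose(deep / top, 2.0, atol=1e-6)

    def test_extreme_flowrate_clamped_non_negative(self):
        with pytest.warns(RuntimeWarning):
            top, deep = interlayer_flow(
                np.array([0.0]), np.array([1.0]), 1.0, 0.1, 1.9
            )
        assert top[0] >= 0 and deep[0] >= 0
        assert top[0] + deep[0] == pytest.approx(1.0)


class TestGradientPlate:
    def test_five_fold_band_matches_uniform_total(self, rect_geometry):
        geom = rect_geometry  # 40 rows
        layers = init_gradient_plate(geom, 2.0, 4.0, 0.5, 0.5, 0.5,
                                     concentration_multiplier=5.0)
        uniform = NutrientLayers.uniform(geom, 2.0, 4.0)
        assert layers.total() == pytest.approx(uniform.total(), rel=1e-12)

    def test_no_prediffusion_leaves_outside_empty(self, rect_geometry):
        layers = init_gradient_plate(rect_geometry, 2.0, 4.0, 0.5, 0.5, 0.5)
        band = int(round(rect_geometry.n_rows * 0.2))
        assert (layers.top[band:, :] == 0).all()
        assert (layers.top[:band, :] > 0).all()

    def test_prediffusion_builds_monotone_gradient(self, rect_geometry):
        layers = init_gradient_plate(
            rect_geometry, 2.0, 4.0, 1.0, 1.0, 0.5, pre_diffusion_steps=50
        )
        profile = (layers.top + layers.deep).mean(axis=1)
        assert profile[0] > profile[-1] > 0
        # totals survive the pre-diffusion rounds
        band = int(round(rect_geometry.n_rows * 0.2))
        assert layers.total() == pytest.approx(band * rect_geometry.n_cols * 6.0, rel=1e-9)

    def test_empty_region_rejected(self):
        geom = PlateGeometry(4, 4, "rectangular")
        with pytest.raises(ValueError):
            init_gradient_plate(geom, 2.0, 4.0, 0.5, 0.5, 0.5,
                                nutrient_fraction_rows=0.01)


class TestRefeed:
    def test_zero_amount_is_noop(self, circle_geometry):
        layers = NutrientLayers.uniform(circle_geometry, 1.0, 2.0)
        before = layers.total()
        apply_refeed(layers, RefeedEvent(step=0, amount=0.0), circle_geometry)
        assert layers.total() == before

    def test_additivity_over_region(self, rect_geometry):
        layers = NutrientLayers.uniform(rect_geometry, 1.0, 2.0)
        region = np.zeros_like(rect_geometry.mask)
        region[0, :10] = True
        before = layers.top.sum()
        added = apply_refeed(
            layers, RefeedEvent(step=0, amount=5.0, region=region, layer="top"),
            rect_geometry,
        )
        assert added == pytest.approx(50.0)
        assert layers.top.sum() - before == pytest.approx(50.0)

    def test_two_events_sum(self, rect_geometry):
        layers = NutrientLayers.uniform(rect_geometry, 1.0, 2.0)
        before = layers.total()
        for _ in range(2):
            apply_refeed(layers, RefeedEvent(step=3, amount=1.0, layer="both"), rect_geometry)
        expected = before + 2 * 2 * 1.0 * rect_geometry.mask.sum()
        assert layers.total() == pytest.approx(expected)

    def test_ring_region_stays_inside_plate(self, circle_geometry):
        ring = circle_geometry.outer_ring(4)
        assert ring.any()
        assert not (ring & ~circle_geometry.mask).any()


class TestGeometry:
    def test_rectangular_mask_all_true(self, rect_geometry):
        assert rect_geometry.mask.all()

    def test_circular_mask_is_inscribed_disc(self):
        geom = PlateGeometry(21, 21, "circular")
        assert geom.mask[10, 10]
        assert not geom.mask[0, 0]
        yy, xx = np.mgrid[0:21, 0:21]
        inside = (yy - 10) ** 2 + (xx - 10) ** 2 <= 10.5**2
        # mask is a disc: no in-mask cell outside the slightly padded circle
        assert not (geom.mask & ~inside).any()

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            PlateGeometry(0, 5, "circular")
        with pytest.raises(ValueError):
            PlateGeometry(5, 5, "hexagonal")
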