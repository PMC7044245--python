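"""Aeration, strain, strain rate, spatial summaries, and the full pipeline."""

import numpy as np
import pytest
from conftest import interior_mask
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ventstrain.regional import (
    aeration_range,
    compute_metric_maps,
    spatial_summary,
    strain_rate_series,
    strain_series,
    trim_mask,
)

SPACING = np.array([0.6, 0.6, 0.6])


class TestTrimMask:
    def test_zero_trim_is_identity(self):
        mask = np.ones((8, 8, 30), dtype=bool)
        assert np.array_equal(trim_mask(mask, SPACING, 0.0), mask)

    def test_six_mm_at_point_six_spacing_removes_ten_slices_per_end(self):
        mask = np.ones((4, 4, 40), dtype=bool)
        out = trim_mask(mask, SPACING, 6.0)
        removed = np.where(~out.any(axis=(0, 1)))[0]
        assert np.array_equal(removed, np.r_[0:10, 30:40])

    def test_thin_mask_errors(self):
        mask = np.ones((4, 4, 15), dtype=bool)  # 9 mm deep, trim 6 mm per end
        with pytest.raises(ValueError):
            trim_mask(mask, SPACING, 6.0)

    def test_negative_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_mask(np.ones((4, 4, 40), dtype=bool), SPACING, -1.0)


class TestAerationRange:
    def test_constant_series_gives_zero(self):
        series = np.full((5, 3, 3, 3), -700.0)
        delta, n_valid = aeration_range(series)
        assert np.all(delta == 0)
        assert np.all(n_valid == 5)

    def test_simple_series(self):
        series = np.array([-900.0, -800.0, -850.0]).reshape(3, 1, 1, 1)
        delta, _ = aeration_range(series)
        assert delta[0, 0, 0] == 100.0

    def test_voxels_with_fewer_than_two_valid_phases_flagged(self):
        series = np.full((3, 2, 1, 1), -700.0)
        valid = np.ones_like(series, dtype=bool)
        valid[:, 1] = False
        valid[0, 1] = True
        delta, n_valid = aeration_range(series, valid)
        assert np.isnan(delta[1, 0, 0])
        assert n_valid[1, 0, 0] == 1

    def test_phantom_aeration_tracks_volume_excursion(self, hfov_case):
        # noiseless intensity model: dI is monotone in the ground-truth
        # volume excursion, so the two correlate strongly over the lung
        _, truth, maps = hfov_case
        interior = interior_mask(truth, maps)
        excursion = truth.det_series.max(axis=0) - truth.det_series.min(axis=0)
        r = np.corrcoef(maps.delta_i[interior], excursion[interior])[0, 1]
        assert r > 0.9


class TestStrain:
    def test_direct_example(self):
        v = np.array([1.0, 1.2, 1.1]).reshape(3, 1, 1, 1)
        eps, d_eps = strain_series(v)
        assert np.allclose(eps.ravel(), [0.0, 0.2, 0.1])
        assert d_eps[0, 0, 0] == pytest.approx(0.2)

    def test_constant_volume_gives_zero_strain(self):
        v = np.full((4, 2, 2, 2), 0.216)
        eps, d_eps = strain_series(v)
        assert np.all(eps == 0) and np.all(d_eps == 0)

    def test_nonpositive_volume_rejected(self):
        v = np.ones((3, 2, 2, 2))
        v[1, 0, 0, 0] = -0.1
        with pytest.raises(ValueError):
            strain_series(v, mask=np.ones((2, 2, 2), dtype=bool))

    def test_min_strain_identically_zero(self, hfov_case):
        _, _, maps = hfov_case
        assert np.all(maps.eps.min(axis=0)[maps.mask] == 0)
        assert np.array_equal(maps.delta_eps, maps.eps.max(axis=0))

    def test_phantom_strain_within_two_percent_of_prescription(self, hfov_case):
        _, truth, maps = hfov_case
        interior = interior_mask(truth, maps)
        d_gt = truth.delta_strain()
        rel = np.abs(maps.delta_eps - d_gt)[interior] / d_gt[interior]
        assert rel.max() < 0.02


class TestStrainRate:
    def test_phase_interval_at_hfov(self):
        # 21 phases at 5 Hz fundamental: 105 Hz effective sampling
        from ventstrain.core import PeriodicImageSequence

        seq = PeriodicImageSequence(
            images=np.zeros((21, 3, 3, 3)),
            masks=np.ones((21, 3, 3, 3), dtype=bool),
            spacing=SPACING,
            f0=5.0,
        )
        assert seq.dt == pytest.approx(1.0 / 105.0)

    def test_forward_difference_with_wraparound(self):
        eps = np.array([0.0, 0.2, 0.1]).reshape(3, 1, 1, 1)
        rate, d_rate = strain_rate_series(eps, dt=0.1)
        assert np.allclose(rate.ravel(), [2.0, -1.0, -1.0])
        assert d_rate[0, 0, 0] == pytest.approx(3.0)

    def test_periodic_rates_integrate_to_zero(self):
        rng = np.random.default_rng(0)
        eps = rng.uniform(0, 0.5, size=(9, 4, 4, 4))
        rate, _ = strain_rate_series(eps, dt=0.05)
        assert np.allclose(rate.sum(axis=0) * 0.05, 0.0, atol=1e-12)

    def test_range_bounds_and_cyclic_invariance(self, hfov_case):
        _, _, maps = hfov_case
        inside = maps.mask
        assert np.all(
            maps.delta_eps_rate[inside]
            >= np.abs(maps.eps_rate).max(axis=0)[inside] - 1e-12
        )
        rolled_rate, rolled_range = strain_rate_series(
            np.roll(maps.eps, 4, axis=0), maps.dt
        )
        assert np.allclose(rolled_range, maps.delta_eps_rate)

    def test_too_few_phases_rejected(self):
        with pytest.raises(ValueError):
            strain_rate_series(np.zeros((1, 2, 2, 2)), 0.1)


class TestSpatialSummary:
    def test_linear_ramp_recovered_exactly(self):
        shape = (8, 10, 6)
        y = np.arange(shape[1]) * SPACING[1]
        field = 3.0 + 2.0 * y[None, :, None] * np.ones(shape)
        mask = np.ones(shape, dtype=bool)
        s = spatial_summary(field, mask, SPACING)
        assert s.slope[1] == pytest.approx(2.0, rel=1e-12)
        assert s.slope[0] == pytest.approx(0.0, abs=1e-12)
        assert s.slope[2] == pytest.approx(0.0, abs=1e-12)
        # CoV of a uniform ramp a + b*y: population std of y times b / mean
        expected_cov = 2.0 * np.std(y) / field.mean()
        assert s.cov == pytest.approx(expected_cov, rel=1e-12)
        assert s.slope_norm[1] == pytest.approx(2.0 / field.mean(), rel=1e-12)

    def test_constant_field(self):
        field = np.full((5, 5, 5), 7.0)
        s = spatial_summary(field, np.ones((5, 5, 5), dtype=bool), SPACING)
        assert s.cov == 0.0
        assert np.all(s.slope == 0)

    def test_zero_mean_flags_normalized_slopes(self):
        field = np.zeros((4, 4, 4))
        s = spatial_summary(field, np.ones((4, 4, 4), dtype=bool), SPACING)
        assert np.all(np.isnan(s.slope_norm))

    def test_phantom_dv_gradient_recovered_within_five_percent(self, hfov_case):
        _, truth, maps = hfov_case
        interior = interior_mask(truth, maps)
        measured = spatial_summary(maps.delta_eps, interior, SPACING)
        reference = spatial_summary(truth.delta_strain(), interior, SPACING)
        assert measured.slope[1] > 0
        assert measured.slope[1] == pytest.approx(reference.slope[1], rel=0.05)


class TestStrainProperties:
    """Invariants over arbitrary admissible volume series."""

    @given(
        arrays(
            float,
            (6, 2, 2, 2),
            elements=st.floats(0.05, 5.0, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_min_strain_zero_and_rate_telescopes(self, v):
        eps, d_eps = strain_series(v)
        assert np.all(eps >= 0)
        assert np.allclose(eps.min(axis=0), 0.0, atol=1e-15)
        assert np.allclose(d_eps, eps.max(axis=0))
        rate, d_rate = strain_rate_series(eps, dt=0.02)
        assert np.allclose(rate.sum(axis=0) * 0.02, 0.0, atol=1e-9)
        assert np.all(d_rate >= np.abs(rate).max(axis=0) - 1e-12)

    @given(st.integers(1, 5))
    @settings(max_examples=6, deadline=None)
    def test_range_metrics_invariant_to_cyclic_relabeling(self, shift):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 2.0, size=(7, 3, 3, 3))
        _, d1 = strain_series(v)
        _, d2 = strain_series(np.roll(v, shift, axis=0))
        assert np.allclose(d1, d2)


class TestReferencePhaseInvariance:
    def test_range_metrics_invariant_to_reference_phase(self, small_hfov_case):
        # the choice of reference phase is arbitrary; metric summaries must
        # agree within interpolation tolerance when a different phase anchors
        # the alignment (this path exercises numeric inversion + composition)
        from scipy.ndimage import binary_erosion

        from ventstrain.transforms import reference_grid_mm, warp_image

        seq, truth = small_hfov_case
        maps0 = compute_metric_maps(seq, truth.transforms, ref_phase=0, trim_mm=2.0)
        maps4 = compute_metric_maps(seq, truth.transforms, ref_phase=4, trim_mm=2.0)
        # bring the ref-4 map onto the ref-0 material points (phi_0 = id, so
        # the frame-0 -> frame-4 mapping is the forward displacement)
        mapping = reference_grid_mm(seq.grid_shape, SPACING) + truth.transforms[4]
        d_eps_4_in_0, ok = warp_image(maps4.delta_eps, mapping, SPACING)
        interior = binary_erosion(truth.mask, iterations=3) & maps0.mask & ok
        rel = np.abs(d_eps_4_in_0 - maps0.delta_eps)[interior] / np.abs(
            maps0.delta_eps[interior]
        )
        assert np.median(rel) < 0.03
        assert np.mean(d_eps_4_in_0[interior]) == pytest.approx(
            np.mean(maps0.delta_eps[interior]), rel=0.03
        )
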