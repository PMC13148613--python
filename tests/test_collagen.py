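"""Collagen meridional analysis: Bragg inversion, peak fits, O/D solver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scansaxs import (compute_d_period, compute_i6_over_i5, default_grid,
                      extract_meridional_profile, fit_peak,
                      forward_intensity_ratio, order_weight,
                      peak_prevalence_table, solve_overlap_fraction)
from scansaxs.collagen import (CollagenPointResult, analyze_collagen_point,
                               nearest_sector_pair, order_window)
from scansaxs.grids import SENTINEL, make_phi_centers
from scansaxs.peakfit import PeakFit
from scansaxs.simulate import collagen_sigma

PHI16 = make_phi_centers(16)


class TestSectorExtraction:
    def test_nearest_pair_oracle(self):
        """Pair choice matches an exhaustive axial-distance search."""
        for theta in np.linspace(0, 179.9, 37):
            k1, k2 = nearest_sector_pair(theta, PHI16)
            assert k2 == k1 + 8
            d = np.abs((PHI16[:8] - theta) % 180.0)
            d = np.minimum(d, 180.0 - d)
            assert d[k1] == d.min()

    def test_theta_zero_picks_first_axis_pair(self):
        # sector centers 11.25 and 348.75 are both 11.25 deg from 0; the
        # lowest-index pair wins the tie
        k1, k2 = nearest_sector_pair(0.0, PHI16)
        assert (k1, k2) == (0, 8)

    def test_theta_90_is_orthogonal_to_theta_0(self):
        k0, _ = nearest_sector_pair(0.0, PHI16)
        k90, _ = nearest_sector_pair(90.0, PHI16)
        assert abs(PHI16[k90] - PHI16[k0]) == pytest.approx(90.0, abs=22.5 / 2)

    def test_isotropic_point_profile_equals_any_sector(self):
        point = np.tile(np.linspace(1, 5, 30), (16, 1))
        prof = extract_meridional_profile(point, 37.0, PHI16)
        np.testing.assert_allclose(prof, point[0])

    def test_one_sentinel_sector_falls_back_to_the_other(self):
        point = np.tile(np.full(30, 4.0), (16, 1))
        k1, k2 = nearest_sector_pair(10.0, PHI16)
        point[k1] = SENTINEL
        prof = extract_meridional_profile(point, 10.0, PHI16)
        np.testing.assert_allclose(prof, 4.0)


class TestBragg:
    def test_identity_case(self):
        assert compute_d_period(1, 2 * math.pi) == pytest.approx(1.0)

    def test_unprocessed_median_arithmetic(self):
        # fresh-tissue fifth-order case: q5 = 2 pi 5 / 66.727 = 0.470813
        assert compute_d_period(5, 2 * math.pi * 5 / 66.727) == pytest.approx(66.727, abs=1e-9)
        assert 2 * math.pi * 5 / 66.727 == pytest.approx(0.47081, abs=1e-5)

    def test_sixth_order_inverse_by_construction(self):
        assert compute_d_period(6, 2 * math.pi * 6 / 67.0) == pytest.approx(67.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1.0, 200.0), st.integers(1, 10))
    def test_bragg_round_trip_exact(self, D, n):
        assert compute_d_period(n, 2 * math.pi * n / D) == pytest.approx(D, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_d_period(5, 0.0)
        with pytest.raises(ValueError):
            compute_d_period(0, 1.0)


class TestPeakFit:
    def test_pure_gaussian_recovered_to_0p1_percent(self):
        grid = default_grid()
        q = grid.q_centers
        prof = 100.0 * np.exp(-0.5 * ((q - 0.47) / 0.005) ** 2)
        f = fit_peak(q, prof, (0.44, 0.50))
        assert f.visible
        assert f.amplitude == pytest.approx(100.0, rel=1e-3)
        assert f.center == pytest.approx(0.47, rel=1e-3)
        assert f.sigma == pytest.approx(0.005, rel=1e-3)

    def test_pure_power_law_invisible(self):
        grid = default_grid()
        q = grid.q_centers
        f = fit_peak(q, 3.0 * q ** -3.0, (0.44, 0.50))
        assert not f.visible

    def test_too_few_bins_invisible_with_message(self):
        q = np.linspace(0.44, 0.50, 5)
        f = fit_peak(q, np.ones(5), (0.44, 0.50))
        assert not f.visible and "bins" in f.message


class TestIntensityRatio:
    def fake_fit(self, area, visible=True):
        sigma = 0.005
        return PeakFit(center=0.5, sigma=sigma, visible=visible,
                       amplitude=area / (sigma * math.sqrt(2 * math.pi)))

    def test_equal_areas_give_one(self):
        assert compute_i6_over_i5(self.fake_fit(2.0), self.fake_fit(2.0)) == pytest.approx(1.0)

    def test_zero_sixth_gives_zero(self):
        assert compute_i6_over_i5(self.fake_fit(2.0), self.fake_fit(0.0)) == pytest.approx(0.0)

    def test_invisible_peak_gives_none(self):
        assert compute_i6_over_i5(self.fake_fit(2.0, visible=False), self.fake_fit(1.0)) is None

    def test_step_model_arithmetic_at_x_042(self):
        # (25/36) sin^2(6 pi 0.42) / sin^2(5 pi 0.42) ~ 7.24
        expect = (25 / 36) * math.sin(6 * math.pi * 0.42) ** 2 / math.sin(5 * math.pi * 0.42) ** 2
        r5, r6 = 1.0, expect
        f5, f6 = self.fake_fit(r5), self.fake_fit(r6)
        assert compute_i6_over_i5(f5, f6) == pytest.approx(7.2436, abs=5e-3)


class TestOverlapSolver:
    def test_hydrated_reference_round_trip(self):
        r = forward_intensity_ratio(0.46, n=5)
        assert solve_overlap_fraction(1.0, r) == pytest.approx(0.46, abs=1e-6)

    def test_zero_sixth_order_gives_half(self):
        # sin(6 pi 0.5) = 0: even orders vanish for symmetric gap/overlap
        assert solve_overlap_fraction(1.0, 0.0) == 0.5

    def test_round_trip_at_043(self):
        r = forward_intensity_ratio(0.43, n=5)
        assert solve_overlap_fraction(1.0, r) == pytest.approx(0.43, abs=1e-6)

    def test_forward_inverse_round_trip_on_grid(self):
        """|x_hat - x| < 1e-5 across [0.38, 0.498] (true branch selected).

        x = 0.40 is excluded: there the fifth order itself is extinguished
        (sin 5 pi x = 0) and the ratio diverges — no inversion exists.
        """
        for x in np.arange(0.38, 0.4981, 0.004):
            if abs(x - 0.40) < 1e-9:
                continue
            r = forward_intensity_ratio(x, n=5)
            x_hat = solve_overlap_fraction(1.0, r, reference=float(x))
            assert x_hat == pytest.approx(x, abs=1e-5)

    def test_default_reference_picks_structurally_reasonable_root(self):
        """Among multiple roots the solver returns the one nearest 0.46."""
        r = forward_intensity_ratio(0.43, n=5)
        # r(0.43) also occurs on the branch below the pole at x = 0.4
        assert solve_overlap_fraction(1.0, r) == pytest.approx(0.43, abs=1e-6)

    def test_monotonicity_of_forward_ratio(self):
        """r(x) strictly decreases over [0.40, 0.50] at 1e-3 spacing."""
        xs = np.arange(0.40, 0.50 + 1e-9, 1e-3)
        r = forward_intensity_ratio(xs, n=5)
        assert r[0] > 1e20   # pole at 0.40 (divergent up to rounding of sin)
        assert np.all(np.diff(r) < 0)

    def test_no_root_returns_none(self):
        # ratios far above anything attainable in the bracket's domain
        assert solve_overlap_fraction(1.0, 1e9, bracket=(0.43, 0.49)) is None

    def test_invalid_intensities_rejected(self):
        with pytest.raises(ValueError):
            solve_overlap_fraction(0.0, 1.0)
        with pytest.raises(ValueError):
            solve_overlap_fraction(1.0, -0.5)


def synthetic_meridional_point(D=66.727, x=0.46, amp=600.0, orders=range(1, 7)):
    """Noiseless [n_seg, n_q] point with step-model weighted orders."""
    grid = default_grid()
    q = grid.q_centers
    prof = 0.5 * q ** -3.0
    for n in orders:
        c = 2 * math.pi * n / D
        s = collagen_sigma(n)
        w = float(order_weight(n, x))
        prof += amp * w * np.exp(-0.5 * ((q - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    return np.tile(prof, (16, 1)), grid


class TestPointAnalysis:
    def test_full_point_recovers_d_ratio_and_overlap(self):
        point, grid = synthetic_meridional_point()
        res = analyze_collagen_point(point, theta_s=0.0, grid=grid)
        assert res.D5 == pytest.approx(66.727, abs=0.05)
        assert res.D6 == pytest.approx(66.727, abs=0.05)
        assert res.i6_over_i5 == pytest.approx(forward_intensity_ratio(0.46, 5), rel=0.02)
        assert res.overlap_fraction == pytest.approx(0.46, abs=0.005)

    def test_fwhm_bias_within_one_bin_width(self):
        """Fitted widths are recovered within the q-bin resolution."""
        point, grid = synthetic_meridional_point()
        res = analyze_collagen_point(point, theta_s=0.0, grid=grid)
        dq = grid.q_centers[1] - grid.q_centers[0]
        true5 = 2 * math.sqrt(2 * math.log(2)) * collagen_sigma(5)
        assert abs(res.fwhm5 - true5) <= dq

    def test_out_of_range_d_flagged_outlier(self):
        # an 80 nm repeat is outside the physiological [55, 75] nm range;
        # widening the window placement to find its peaks must flag the
        # point instead of reporting the value
        point, grid = synthetic_meridional_point(D=80.0)
        res = analyze_collagen_point(point, theta_s=0.0, grid=grid,
                                     d_nominal=80.0)
        assert np.isnan(res.D5) and res.outlier


class TestPrevalenceTable:
    def make_result(self, areas: dict):
        res = CollagenPointResult()
        for n, area in areas.items():
            sigma = 0.004
            res.peak_fits[n] = PeakFit(
                order=n, center=2 * math.pi * n / 67.0, sigma=sigma,
                amplitude=area / (sigma * math.sqrt(2 * math.pi)), visible=True)
        return res

    def test_identical_points_give_common_ratios(self):
        areas = {1: 10.0, 2: 1.0, 5: 4.0}
        results = [self.make_result(areas) for _ in range(5)]
        tab = peak_prevalence_table(results)
        a = tab.set_index("order")["A_median_norm_intensity"]
        assert a[1] == pytest.approx(1.0)
        assert a[2] == pytest.approx(0.1)
        assert a[5] == pytest.approx(0.4)

    def test_never_visible_order_has_zero_fraction(self):
        results = [self.make_result({1: 10.0, 5: 4.0}) for _ in range(4)]
        tab = peak_prevalence_table(results).set_index("order")
        assert tab.loc[2, "B_visible_fraction"] == 0.0
        assert pd.isna(tab.loc[2, "A_median_norm_intensity"])
        assert tab.loc[5, "B_visible_fraction"] == 1.0

    def test_order_one_never_visible_keeps_b_reported(self):
        results = [self.make_result({5: 4.0, 6: 2.0}) for _ in range(3)]
        tab = peak_prevalence_table(results).set_index("order")
        assert pd.isna(tab.loc[5, "A_median_norm_intensity"])
        assert tab.loc[5, "B_visible_fraction"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            peak_prevalence_table([])

    def test_unprocessed_preset_damps_even_orders(self):
        """Fresh hydrated tissue (x ~ 0.46): odd orders prominent, order 2
        nearly absent — reproduced by the simulator preset."""
        point, grid = synthetic_meridional_point(orders=range(1, 11))
        res = analyze_collagen_point(point, theta_s=0.0, grid=grid,
                                     orders=tuple(range(1, 11)))
        tab = peak_prevalence_table([res]).set_index("order")
        # even-order weights at x = 0.46 are tiny; order 2 under 2% of order 1
        a = tab["A_median_norm_intensity"]
        if a[2] is not None:
            assert a[2] < 0.05
        assert tab.loc[5, "B_visible_fraction"] == 1.0
        assert tab.loc[6, "B_visible_fraction"] == 1.0
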