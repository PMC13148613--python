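"""Simulator: determinism, forward-model correctness, preset library."""

import math

import numpy as np
import pytest

from scansaxs import (DetectorGeometry, default_grid, get_preset,
                      make_ground_truth, preset_library, reduce_frame,
                      simulate_detector_frame, simulate_reduced_scan)
from scansaxs.scan import (REGION_BACKGROUND, REGION_COLLAGEN, REGION_MUSCLE,
                           REGION_OTHER)
from scansaxs.simulate import (D_UNPROCESSED_NM, MUSCLE_SIGMA, collagen_sigma,
                               expected_point_intensity)


class TestGroundTruth:
    def test_same_seed_is_identical(self):
        a = make_ground_truth("unprocessed", 12, 12, seed=5)
        b = make_ground_truth("unprocessed", 12, 12, seed=5)
        np.testing.assert_array_equal(a.label, b.label)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.D, b.D)

    def test_different_seeds_differ(self):
        a = make_ground_truth("unprocessed", 12, 12, seed=5)
        b = make_ground_truth("unprocessed", 12, 12, seed=6)
        assert not np.array_equal(a.label, b.label)

    def test_collagen_fraction_in_configured_range(self):
        gt = make_ground_truth("unprocessed", 40, 40, seed=7,
                               region_fractions=(0.45, 0.35))
        interior = gt.label[1:-1, 1:-1]
        frac = (interior == REGION_COLLAGEN).mean()
        assert 0.30 <= frac <= 0.60   # quantile thresholding +- border effects

    def test_border_is_background(self):
        gt = make_ground_truth("unprocessed", 12, 12, seed=5)
        assert np.all(gt.label[0] == REGION_BACKGROUND)
        assert np.all(gt.label[:, -1] == REGION_BACKGROUND)

    def test_too_small_mosaic_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth("unprocessed", 4, 12, seed=0)


class TestForwardModel:
    def test_scan_determinism_byte_identical(self):
        grid = default_grid(n_q=300)
        gt = make_ground_truth("unprocessed", 10, 10, seed=3)
        a = simulate_reduced_scan(gt, grid, seed=4)
        b = simulate_reduced_scan(gt, grid, seed=4)
        assert a.intensity.tobytes() == b.intensity.tobytes()

    def test_kappa_zero_is_azimuthally_uniform(self):
        grid = default_grid(n_q=300)
        gt = make_ground_truth("unprocessed", 10, 10, seed=3)
        gt.kappa = 0.0
        i, j = np.argwhere(gt.label == REGION_COLLAGEN)[0]
        lam = expected_point_intensity(gt, i, j, grid)
        np.testing.assert_allclose(lam, np.tile(lam[0], (16, 1)))

    def test_even_orders_vanish_at_symmetric_overlap(self):
        """x = 0.5: only background in even-order collagen windows."""
        grid = default_grid()
        gt = make_ground_truth("unprocessed", 10, 10, seed=3)
        gt.overlap_x[:] = 0.5
        i, j = np.argwhere(gt.label == REGION_COLLAGEN)[0]
        lam = expected_point_intensity(gt, i, j, grid)
        q = grid.q_centers
        D = gt.D[i, j]
        bg = gt.background_scale * q ** -gt.background_exponent + gt.floor
        for n in (2, 4, 6):
            c = 2 * math.pi * n / D
            sel = np.abs(q - c) < 2 * collagen_sigma(n)
            np.testing.assert_allclose(lam[:, sel], np.tile(bg[sel], (16, 1)),
                                       rtol=1e-8)

    def test_expected_bins_match_independent_formula(self):
        """Direct re-evaluation of the forward model at 5 random points."""
        grid = default_grid(n_q=400)
        gt = make_ground_truth("unprocessed", 12, 12, seed=9)
        rng = np.random.default_rng(0)
        q, phi = grid.q_centers, grid.phi_centers
        pts = rng.choice(12 * 12, size=5, replace=False)
        for flat in pts:
            i, j = divmod(int(flat), 12)
            lam = expected_point_intensity(gt, i, j, grid)
            lab = gt.label[i, j]
            if lab == REGION_BACKGROUND:
                expect = np.full((16, q.size), gt.floor)
            else:
                expect = np.tile(gt.background_scale * q ** -3.0 + gt.floor,
                                 (16, 1))
                if lab == REGION_COLLAGEN:
                    radial = np.zeros_like(q)
                    for n in range(1, 11):
                        c = 2 * math.pi * n / gt.D[i, j]
                        s = 0.0025 * math.sqrt(n)
                        if c > q[-1] + 5 * s:
                            continue
                        w = (math.sin(math.pi * n * gt.overlap_x[i, j]) ** 2
                             / (math.pi * n) ** 2) * gt.order_multipliers[n - 1]
                        radial += w * np.exp(-0.5 * ((q - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
                    K = np.exp(gt.kappa * (np.cos(2 * np.radians(phi - gt.theta[i, j])) - 1))
                    expect = expect + gt.collagen_amplitude[i, j] * K[:, None] * radial[None, :]
                elif lab == REGION_MUSCLE:
                    d10 = gt.muscle_d10[i, j]
                    d11 = d10 / math.sqrt(3)
                    s = MUSCLE_SIGMA
                    radial = (np.exp(-0.5 * ((q - 2 * math.pi / d10) / s) ** 2)
                              + gt.i11_over_i10[i, j]
                              * np.exp(-0.5 * ((q - 2 * math.pi / d11) / s) ** 2)
                              ) / (s * math.sqrt(2 * math.pi))
                    K = np.exp(gt.kappa_m * (np.cos(2 * np.radians(phi - gt.theta[i, j] - 90)) - 1))
                    expect = expect + gt.muscle_amplitude[i, j] * K[:, None] * radial[None, :]
                else:
                    radial = sum(np.exp(-0.5 * ((q - c) / 0.012) ** 2)
                                 for c in (0.075, 0.16, 0.245))
                    expect = expect + gt.other_amplitude * radial[None, :]
            np.testing.assert_allclose(lam, expect, rtol=1e-10)


class TestDetectorFrames:
    def test_frame_reduction_matches_reduced_scan_in_expectation(self):
        geom = DetectorGeometry()
        gt = make_ground_truth("unprocessed", 10, 10, seed=17)
        i, j = map(int, np.argwhere(gt.label == REGION_COLLAGEN)[0])
        grid = default_grid(n_q=200, q_min=0.06, q_max=0.60)
        frame = simulate_detector_frame(gt, i, j, geom, grid=grid, seed=1,
                                        noise=False)
        slab = reduce_frame(frame, grid)
        lam = expected_point_intensity(gt, i, j, grid)
        # pixel (q, phi) varies inside each bin, so compare loosely away
        # from the steep low-q region and only on populated bins
        sel = slab >= 0
        sel[:, grid.q_centers < 0.2] = False
        ratio = slab[sel] / lam[sel]
        assert np.median(np.abs(ratio - 1)) < 0.05

    def test_masked_ring_gives_sentinel_bins(self):
        geom = DetectorGeometry()
        q, _ = geom.pixel_q_phi((256, 256))
        geom.mask = (q > 0.3) & (q < 0.35)
        gt = make_ground_truth("unprocessed", 10, 10, seed=17)
        grid = default_grid(n_q=200, q_min=0.06, q_max=0.60)
        frame = simulate_detector_frame(gt, 5, 5, geom, grid=grid, seed=1)
        slab = reduce_frame(frame, grid)
        ring = (grid.q_centers > 0.31) & (grid.q_centers < 0.34)
        assert np.all(slab[:, ring] < 0)

    def test_background_point_is_pure_floor(self):
        geom = DetectorGeometry()
        gt = make_ground_truth("unprocessed", 10, 10, seed=17)
        i, j = map(int, np.argwhere(gt.label == REGION_BACKGROUND)[0])
        frame = simulate_detector_frame(gt, i, j, geom, seed=1, noise=False)
        np.testing.assert_allclose(frame.counts, gt.floor)


class TestPresets:
    def test_library_has_at_least_five_named_presets(self):
        lib = preset_library()
        names = {p.name for p in lib}
        assert len(lib) >= 5 and len(names) == len(lib)
        assert {"unprocessed", "dehydrated", "tough_resin", "paraffin",
                "cryo"} <= names

    def test_unprocessed_reference_values(self):
        p = get_preset("unprocessed")
        assert p.overlap_x == 0.46
        assert p.d_nm == pytest.approx(66.727)
        assert p.muscle

    def test_tough_resin_shrinkage_arithmetic(self):
        p = get_preset("tough_resin")
        assert p.d_nm == pytest.approx(66.727 * (1 - 0.0364))

    def test_dehydrated_loses_muscle_and_overlap(self):
        p = get_preset("dehydrated")
        assert not p.muscle
        assert p.overlap_x == pytest.approx(0.42)
        assert p.d_nm < D_UNPROCESSED_NM * 0.985

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("formaldehyde-vapour")
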