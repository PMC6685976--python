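"""Distance analysis, square-geometry classification and frequency summaries."""

import numpy as np
import pytest
from oracles import brute_ks_statistic, brute_min_distance_to_mask

from flickermap.errors import DegenerateInputError, ParameterError
from flickermap.fret import ForceRegionMask
from flickermap.io_ import CellMask
from flickermap.spatial import (
    SquareGeometry,
    analyze_distances,
    classify_square_regions,
    compare_distributions_ks,
    distance_to_force_regions,
    flicker_frequency,
    random_null_distances,
    region_chi_square,
)


def _regions(mask):
    return ForceRegionMask(mask=np.asarray(mask, bool), blur_sigma=2.0,
                           threshold_fraction=0.75, reference_max=1.0)


class TestDistances:
    def test_centroid_on_mask_pixel_is_zero(self):
        mask = np.zeros((16, 16), bool)
        mask[5, 7] = True
        d = distance_to_force_regions([(7.0, 5.0)], _regions(mask), pixel_size=1.0)
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True
        d = distance_to_force_regions([(3.0, 4.0)], _regions(mask), pixel_size=1.0)
        assert d[0] == pytest.approx(5.0, abs=1e-6)

    def test_pixel_size_scales_distances(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True
        d = distance_to_force_regions([(3.0, 4.0)], _regions(mask), pixel_size=0.2)
        assert d[0] == pytest.approx(1.0, abs=1e-6)

    def test_random_cases_match_bruteforce_within_half_pixel(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            mask = np.zeros((32, 32), bool)
            n_pix = rng.integers(1, 20)
            mask[rng.integers(0, 32, n_pix), rng.integers(0, 32, n_pix)] = True
            pt = rng.uniform(0, 31, size=2)
            d = distance_to_force_regions([tuple(pt)], _regions(mask),
                                          pixel_size=1.0)[0]
            ref = brute_min_distance_to_mask(pt, mask)
            assert abs(d - ref) <= 0.5

    def test_empty_mask_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            distance_to_force_regions([(1.0, 1.0)],
                                      _regions(np.zeros((8, 8), bool)), 1.0)

    def test_outside_image_flagged_nan(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        d = distance_to_force_regions([(100.0, 2.0), (4.0, 4.0)],
                                      _regions(mask), 1.0)
        assert np.isnan(d[0]) and np.isfinite(d[1])


class TestNullDistances:
    def _disk_cell(self, r=40, size=100):
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        return CellMask(mask=(xx - c) ** 2 + (yy - c) ** 2 <= r**2, pixel_size=1.0)

    def test_regions_covering_cell_give_zero(self):
        cell = self._disk_cell()
        d = random_null_distances(cell, _regions(cell.mask), n=200, seed=1)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_same_seed_reproducible(self):
        cell = self._disk_cell()
        mask = np.zeros_like(cell.mask)
        mask[50, 50] = True
        d1 = random_null_distances(cell, _regions(mask), n=300, seed=42)
        d2 = random_null_distances(cell, _regions(mask), n=300, seed=42)
        np.testing.assert_array_equal(d1, d2)
        d3 = random_null_distances(cell, _regions(mask), n=300, seed=43)
        assert not np.array_equal(d1, d3)

    def test_disk_mean_distance_matches_closed_form(self):
        # uniform points in a disk of radius R: E[distance to center] = 2R/3
        R = 40
        cell = self._disk_cell(r=R)
        mask = np.zeros_like(cell.mask)
        mask[49, 49] = True  # pixel nearest the disk center (99x99 grid center 49.5)
        d = random_null_distances(cell, _regions(mask), n=20000, seed=5)
        assert d.mean() == pytest.approx(2 * R / 3, rel=0.02)

    def test_empty_cell_is_degenerate(self):
        cell = CellMask(mask=np.zeros((8, 8), bool), pixel_size=1.0)
        with pytest.raises(DegenerateInputError):
            random_null_distances(cell, _regions(np.ones((8, 8), bool)), n=10)


class TestKS:
    def test_identical_samples_statistic_zero(self):
        a = np.arange(50, dtype=float)
        stat, p = compare_distributions_ks(a, a.copy())
        assert stat == pytest.approx(0.0)

    def test_disjoint_samples_statistic_one(self):
        stat, _ = compare_distributions_ks(np.zeros(30), np.ones(30))
        assert stat == pytest.approx(1.0)

    def test_matches_bruteforce_ecdf_sweep(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.3, 1.2, 100)
        stat, _ = compare_distributions_ks(a, b)
        assert stat == pytest.approx(brute_ks_statistic(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            compare_distributions_ks([], [1.0])


class TestSquares:
    def test_center_is_middle_corner_is_corner(self):
        geom = SquareGeometry(side=40.0, corner_fraction=0.25)
        labels = classify_square_regions(
            [(20.0, 20.0), (5.0, 5.0), (20.0, 3.0), (50.0, 20.0)], geom
        )
        assert labels.tolist() == ["middle", "corner", "edge", "outside"]

    def test_areas_sum_to_side_squared(self):
        geom = SquareGeometry(side=45.0, corner_fraction=0.2)
        assert sum(geom.areas.values()) == pytest.approx(45.0**2)

    def test_uniform_points_match_area_fractions(self):
        rng = np.random.default_rng(2)
        geom = SquareGeometry(side=32.0, corner_fraction=0.25)
        pts = rng.uniform(0, 32.0, size=(100_000, 2))
        labels = classify_square_regions(pts, geom)
        total = geom.side**2
        for name, area in geom.areas.items():
            frac = np.mean(labels == name)
            assert frac == pytest.approx(area / total, abs=0.01)

    def test_invalid_corner_fraction_rejected(self):
        with pytest.raises(ParameterError):
            SquareGeometry(side=10.0, corner_fraction=0.6)


class TestChiSquare:
    def test_area_proportional_counts_give_zero(self):
        geom = SquareGeometry(side=40.0, corner_fraction=0.25)
        # areas: corner 0.25, edge 0.5, middle 0.25 of the square
        labels = (["corner"] * 25 + ["edge"] * 50 + ["middle"] * 25)
        rc = region_chi_square(np.array(labels), geom)
        assert rc.chi2 == pytest.approx(0.0, abs=1e-12)
        assert rc.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic_equal_thirds(self):
        # observed (50, 30, 20) against equal expected 33.33 each:
        # chi2 = sum (obs - 100/3)^2 / (100/3) = 14.0
        geom = SquareGeometry(side=1.0, corner_fraction=0.25)
        labels = ["corner"] * 50 + ["edge"] * 30 + ["middle"] * 20
        rc = region_chi_square(np.array(labels), geom, expectation="equal")
        assert rc.chi2 == pytest.approx(14.0, abs=0.01)
        assert rc.df == 2

    def test_uniform_points_calibrated(self):
        geom = SquareGeometry(side=30.0, corner_fraction=0.25)
        from scipy import stats as sps

        crit = sps.chi2.ppf(0.95, df=2)
        hits = 0
        for seed in range(100):
            pts = np.random.default_rng(seed).uniform(0, 30.0, size=(200, 2))
            rc = region_chi_square(classify_square_regions(pts, geom), geom)
            hits += rc.chi2 < crit
        assert hits >= 93

    def test_chi_square_zero_iff_observed_equals_expected(self):
        geom = SquareGeometry(side=40.0, corner_fraction=0.25)
        labels = ["corner"] * 26 + ["edge"] * 50 + ["middle"] * 24
        rc = region_chi_square(np.array(labels), geom)
        assert rc.chi2 > 0


class TestFrequency:
    def _cell(self, n_px=1000):
        mask = np.zeros((100, 100), bool)
        mask.flat[:n_px] = True
        return CellMask(mask=mask, pixel_size=1.0)

    def test_zero_events_zero_frequency(self):
        s = flicker_frequency(0, self._cell(), duration=100.0)
        assert s.frequency == 0.0

    def test_arithmetic(self):
        s = flicker_frequency(10, self._cell(1000), duration=100.0)
        assert s.frequency == pytest.approx(1e-4)
        assert s.frequency_per_1e4 == pytest.approx(1.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ParameterError):
            flicker_frequency(1, self._cell(), duration=0.0)

    def test_poisson_rate_recovery(self, rng):
        # events drawn at rate lam per um^2 per s; estimator within 3/sqrt(N)
        lam, area, dur = 2e-4, 5000.0, 200.0
        expect = lam * area * dur
        n = rng.poisson(expect)
        cell = self._cell(5000)
        s = flicker_frequency(int(n), cell, duration=dur)
        assert abs(s.frequency - lam) / lam <= 3 / np.sqrt(expect)


def test_flickers_near_force_regions_separate_from_null():
    """Flickers implanted adjacent to force regions give mean_exp < mean_null
    and a decisive KS rejection, across 20 seeds."""
    from flickermap.synthetic import generate_force_scene

    wins = 0
    for seed in range(20):
        truth = generate_force_scene(seed=seed, noise_sigma=0.0)
        regions = _regions(truth.force > 4.0)
        rng = np.random.default_rng(1000 + seed)
        jitter = rng.normal(0, 2.0, size=truth.hotspot_centers.shape)
        centroids = np.repeat(truth.hotspot_centers, 8, axis=0) + np.repeat(
            jitter, 8, axis=0) + rng.normal(0, 1.5, (len(truth.hotspot_centers) * 8, 2))
        ana = analyze_distances(centroids, truth.cell, regions,
                                n_null=500, seed=seed)
        if ana.mean_exp < ana.mean_null and ana.p_value < 0.01:
            wins += 1
    assert wins >= 19
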