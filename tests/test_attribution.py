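import math

import numpy as np
import pytest

from dustgeo.attribution import (
    AttributionResult,
    GmmFit,
    Thresholds,
    at5pe,
    attribute_surface,
    classify,
    density_grid,
    fit_gmm,
    haversine,
    summarize_cohort,
    top5_peaks,
    truth_percentage,
)
from dustgeo.errors import EmptySurfaceError, OffGridError
from dustgeo.geogrid import GridSpec, GridSurface, cell_centroid, cell_centroid_lonlat


def surface_from_array(arr, spec, n_otus=10):
    values = {
        (r, c): float(arr[r, c])
        for r in range(spec.nrows)
        for c in range(spec.ncols)
        if arr[r, c] > 0
    }
    return GridSurface(spec=spec, values=values, n_otus=n_otus)


def brute_force_tp(arr, truth_cell):
    """Independent strict-less count over the full extent."""
    tv = arr[truth_cell]
    n_less = sum(
        1 for r in range(arr.shape[0]) for c in range(arr.shape[1]) if arr[r, c] < tv
    )
    return 100.0 * n_less / arr.size


class TestHaversine:
    def test_identity_and_symmetry(self):
        a, b = (-71.23, 42.44), (-106.89, 34.06)
        assert haversine(a, a) == 0.0
        assert haversine(a, b) == pytest.approx(haversine(b, a))

    def test_quarter_great_circle_closed_form(self):
        assert haversine((0.0, 0.0), (0.0, 90.0)) == pytest.approx(
            math.pi * 6371.0 / 2.0, abs=1e-6
        )
        assert haversine((0.0, 0.0), (0.0, 90.0)) == pytest.approx(10007.54, abs=0.01)


class TestAt5pe:
    def test_all_peaks_at_truth(self):
        truth = (-71.23, 42.44)
        assert at5pe([truth] * 5, truth) == 0.0

    def test_mean_of_known_distances(self):
        # peaks placed along the equator at 100..500 km from the origin
        truth = (0.0, 0.0)
        km_per_deg = math.pi * 6371.0 / 180.0
        peaks = [(d / km_per_deg, 0.0) for d in (100, 200, 300, 400, 500)]
        assert at5pe(peaks, truth) == pytest.approx(300.0, abs=1e-6)

    def test_outlier_shifts_mean_by_fifth(self):
        truth = (0.0, 0.0)
        km_per_deg = math.pi * 6371.0 / 180.0
        base = [(d / km_per_deg, 0.0) for d in (100, 100, 100, 100, 100)]
        outlier = base[:4] + [(2100 / km_per_deg, 0.0)]
        assert at5pe(outlier, truth) - at5pe(base, truth) == pytest.approx(2000 / 5, abs=1e-6)

    def test_wrong_peak_count_rejected(self):
        with pytest.raises(ValueError, match="5 peaks"):
            at5pe([(0.0, 0.0)] * 4, (0.0, 0.0))


class TestTruthPercentage:
    def test_unique_maximum_on_ten_cells(self):
        spec = GridSpec(cell_km=250.0, width_km=1250.0, height_km=500.0)  # 10 cells
        arr = np.full((2, 5), 0.1)
        arr[1, 2] = 0.9
        surf = surface_from_array(arr, spec)
        truth = cell_centroid_lonlat(1, 2, spec)
        assert truth_percentage(surf, truth) == pytest.approx(90.0)

    def test_uniform_surface_scores_zero(self):
        spec = GridSpec(cell_km=250.0, width_km=1250.0, height_km=500.0)
        surf = surface_from_array(np.full((2, 5), 0.4), spec)
        assert truth_percentage(surf, cell_centroid_lonlat(0, 0, spec)) == 0.0

    def test_five_cell_example_counts_strictly_less(self):
        spec = GridSpec(cell_km=250.0, width_km=1250.0, height_km=250.0)  # 5 cells
        arr = np.array([[0.1, 0.2, 0.2, 0.3, 0.5]])
        surf = surface_from_array(arr, spec)
        truth = cell_centroid_lonlat(0, 3, spec)  # the 0.3 cell
        assert truth_percentage(surf, truth) == pytest.approx(60.0)

    def test_truth_outside_extent_errors(self, small_grid):
        surf = surface_from_array(np.ones((small_grid.nrows, small_grid.ncols)), small_grid)
        with pytest.raises(OffGridError):
            truth_percentage(surf, (0.0, 0.0))  # Gulf of Guinea, far off-grid

    def test_matches_brute_force_on_random_surfaces(self, small_grid, rng):
        for _ in range(50):
            arr = np.round(rng.random((small_grid.nrows, small_grid.ncols)), 2)
            arr[arr < 0.3] = 0.0
            surf = surface_from_array(arr, small_grid)
            r = rng.integers(small_grid.nrows)
            c = rng.integers(small_grid.ncols)
            truth = cell_centroid_lonlat(int(r), int(c), small_grid)
            assert truth_percentage(surf, truth) == pytest.approx(
                brute_force_tp(arr, (int(r), int(c)))
            )

    def test_sharpening_toward_truth_never_decreases_tp(self, small_grid, rng):
        arr = rng.random((small_grid.nrows, small_grid.ncols))
        truth_cell = (1, 3)
        truth = cell_centroid_lonlat(*truth_cell, small_grid)
        last = -1.0
        for boost in np.linspace(0.0, 1.0, 8):
            boosted = arr.copy()
            boosted[truth_cell] = arr[truth_cell] + boost
            tp = truth_percentage(surface_from_array(boosted, small_grid), truth)
            assert tp >= last
            last = tp


class TestClassify:
    @pytest.mark.parametrize(
        ("tp", "err", "expected"),
        [
            (92.0, 450.0, True),
            (92.0, 700.0, False),
            (89.9, 100.0, False),
            (90.0, 599.99, True),  # TP boundary is inclusive, AT5PE exclusive
            (90.0, 600.0, False),
            (float("nan"), 100.0, False),
        ],
    )
    def test_decision_boundaries(self, tp, err, expected):
        assert classify(tp, err) is expected


class TestFitGmm:
    def test_single_cell_mass_degenerate_fit(self, small_grid):
        arr = np.zeros((small_grid.nrows, small_grid.ncols))
        arr[2, 2] = 1.0
        fit = fit_gmm(surface_from_array(arr, small_grid), seed=0)
        assert fit.n_effective_components == 1
        (w, mean, _), = fit.components
        cx, cy = cell_centroid(2, 2, small_grid)
        assert abs(mean[0] - cx) < small_grid.cell_km / 2
        assert abs(mean[1] - cy) < small_grid.cell_km / 2

    def test_two_distant_clusters_recovered(self):
        spec = GridSpec()  # 24 x 16 conterminous-US default
        arr = np.zeros((spec.nrows, spec.ncols))
        left = [(7, 3), (7, 4), (8, 3), (8, 4)]
        right = [(7, 12), (7, 13), (8, 12), (8, 13)]  # ~2000 km east
        for cell in left:
            arr[cell] = 0.9
        for cell in right:
            arr[cell] = 0.6
        fit = fit_gmm(surface_from_array(arr, spec), seed=0)
        assert fit.n_effective_components >= 2
        for cells, frac in [(left, 0.9), (right, 0.6)]:
            centroid = np.mean([cell_centroid(r, c, spec) for r, c in cells], axis=0)
            nearest = min(
                np.hypot(*(m - centroid)) for _, m, _ in fit.components
            )
            assert nearest < 250.0

    def test_same_seed_bit_identical(self, small_grid, rng):
        arr = rng.random((small_grid.nrows, small_grid.ncols))
        surf = surface_from_array(arr, small_grid)
        a = fit_gmm(surf, seed=7)
        b = fit_gmm(surf, seed=7)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)

    def test_weights_normalized_and_covariances_pd(self, small_grid, rng):
        arr = rng.random((small_grid.nrows, small_grid.ncols))
        fit = fit_gmm(surface_from_array(arr, small_grid), seed=1)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        for cov in fit.covariances:
            assert np.allclose(cov, cov.T)
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_empty_surface_rejected(self, small_grid):
        with pytest.raises(EmptySurfaceError):
            fit_gmm(GridSurface(spec=small_grid, values={}, n_otus=1), seed=0)


class TestTop5Peaks:
    def _manual_fit(self, spec, cells, weights, sigma=100.0):
        means = np.array([cell_centroid(r, c, spec) for r, c in cells])
        covs = np.array([np.eye(2) * sigma**2 for _ in cells])
        return GmmFit(
            weights=np.asarray(weights, float),
            means=means,
            covariances=covs,
            seed=0,
            converged=True,
            k_max=10,
        )

    def test_density_mode_returns_five_densest_cells(self, small_grid):
        fit = self._manual_fit(small_grid, [(2, 2)], [1.0])
        surf = surface_from_array(np.ones((small_grid.nrows, small_grid.ncols)), small_grid)
        peaks = top5_peaks(fit, surf, mode="density")
        D = density_grid(fit, small_grid)
        order = sorted(
            ((r, c) for r in range(small_grid.nrows) for c in range(small_grid.ncols)),
            key=lambda rc: (-D[rc], rc[0], rc[1]),
        )
        expected = [cell_centroid_lonlat(r, c, small_grid) for r, c in order[:5]]
        assert np.allclose(np.array(peaks), np.array(expected))
        # the mode cell itself is the first peak
        assert peaks[0] == pytest.approx(cell_centroid_lonlat(2, 2, small_grid))

    def test_local_maxima_mode_two_modes_then_fill(self, small_grid):
        fit = self._manual_fit(small_grid, [(1, 0), (2, 4)], [0.6, 0.4])
        surf = surface_from_array(np.ones((small_grid.nrows, small_grid.ncols)), small_grid)
        peaks = top5_peaks(fit, surf, mode="local_maxima")
        assert peaks[0] == pytest.approx(cell_centroid_lonlat(1, 0, small_grid))
        assert peaks[1] == pytest.approx(cell_centroid_lonlat(2, 4, small_grid))
        assert len(peaks) == 5  # remaining slots filled by densest non-maxima

    def test_count_mode_tie_breaks_by_row_col(self, small_grid):
        arr = np.zeros((small_grid.nrows, small_grid.ncols))
        arr[0, 1] = arr[3, 2] = 0.8  # tied maxima
        arr[1, 1] = 0.5
        surf = surface_from_array(arr, small_grid)
        fit = self._manual_fit(small_grid, [(0, 0)], [1.0])
        peaks = top5_peaks(fit, surf, mode="count")
        assert peaks[0] == pytest.approx(cell_centroid_lonlat(0, 1, small_grid))
        assert peaks[1] == pytest.approx(cell_centroid_lonlat(3, 2, small_grid))

    def test_unknown_mode_rejected(self, small_grid):
        fit = self._manual_fit(small_grid, [(0, 0)], [1.0])
        surf = surface_from_array(np.ones((small_grid.nrows, small_grid.ncols)), small_grid)
        with pytest.raises(ValueError, match="peak mode"):
            top5_peaks(fit, surf, mode="bogus")


class TestAttributeSurface:
    def test_concentrated_surface_attributes_to_truth(self, small_grid):
        arr = np.zeros((small_grid.nrows, small_grid.ncols))
        arr[2, 2] = 1.0
        arr[2, 3] = 0.6
        surf = surface_from_array(arr, small_grid)
        truth = cell_centroid_lonlat(2, 2, small_grid)
        res = attribute_surface(surf, truth, sample_id="s1", seed=0)
        assert res.positive
        assert res.tp > 89.0
        assert res.at5pe < 600.0
        assert res.n_mapped_otus == surf.n_otus

    def test_peak_order_invariance_of_at5pe(self, small_grid):
        truth = (-98.0, 39.5)
        peaks = [(-98.0, 40.0), (-97.0, 39.0), (-99.0, 39.0), (-98.5, 41.0), (-96.0, 39.5)]
        fwd = at5pe(peaks, truth)
        rev = at5pe(list(reversed(peaks)), truth)
        assert fwd == pytest.approx(rev)


class TestSummarizeCohort:
    def _result(self, sid, site, tp, err, n_otus=25):
        return AttributionResult(
            sample_id=sid, n_mapped_otus=n_otus, tp=tp, at5pe=err,
            peaks=tuple([(0.0, 0.0)] * 5), positive=classify(tp, err), site=site,
        )

    def test_single_positive_sample_is_100_percent(self):
        df = summarize_cohort([self._result("s", "MA", 95.0, 200.0)])
        row = df[df.site == "all sites"].iloc[0]
        assert row.pct_positive == 100.0

    def test_empty_cohort_zero_counts(self):
        df = summarize_cohort([])
        row = df.iloc[0]
        assert row.n == 0 and row.positive == 0
        assert row.pct_positive is None

    def test_stratum_counts_and_unattributable_in_denominator(self):
        from dustgeo.attribution import unattributable

        results = [
            self._result("a", "MA", 95.0, 200.0, n_otus=25),
            self._result("b", "MA", 95.0, 200.0, n_otus=5),
            self._result("c", "MA", 50.0, 900.0, n_otus=25),
            unattributable("d", site="MA"),
        ]
        row = summarize_cohort(results).iloc[0]
        assert row.n == 4
        assert row.positive == 2
        assert row.n_ge20 == 2 and row.positive_ge20 == 1
        assert row.pct_positive == 50.0
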