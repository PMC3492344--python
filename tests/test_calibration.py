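import itertools

import numpy as np
import pytest

from flyfluor import (
    CalibrationLandscape,
    LabeledScores,
    best_threshold,
    select_robust_operating_point,
    sweep_thresholds,
    weight_threshold_landscape,
)
from flyfluor.calibration import DEFAULT_WEIGHT_GRID, combine_scores
from flyfluor.errors import NonSeparableWarning
from flyfluor.io_data import Label


def labeled(scores, truth):
    return LabeledScores(np.arange(len(scores)), np.asarray(scores), np.asarray(truth))


def accuracy_oracle(scores, truth, thr):
    """Direct per-fly evaluation of the >=-threshold-is-GFP rule."""
    correct = sum(
        1 for s, t in zip(scores, truth) if (s >= thr) == t
    )
    return 100.0 * correct / len(scores)


class TestSweepThresholds:
    def test_separable_four_point_orderings_reach_100(self):
        # exhaustive: any assignment of {0,1} non-GFP / {2,3} GFP scores
        for perm in itertools.permutations([(0.0, False), (1.0, False), (2.0, True), (3.0, True)]):
            scores = [p[0] for p in perm]
            truth = [p[1] for p in perm]
            _, acc = sweep_thresholds(labeled(scores, truth), 100)
            assert acc.max() == 100.0

    def test_exactly_requested_threshold_count(self):
        thr, acc = sweep_thresholds(labeled([0.0, 1.0], [False, True]), 1000)
        assert len(thr) == 1000 and len(acc) == 1000
        assert thr[0] == 0.0 and thr[-1] == 1.0

    def test_accuracy_matches_per_fly_oracle(self, rng):
        scores = rng.uniform(0, 1, size=24)
        truth = rng.uniform(0, 1, size=24) > 0.5
        truth[0], truth[1] = True, False  # both classes present
        thr, acc = sweep_thresholds(labeled(scores, truth), 257)
        for t, a in zip(thr[::16], acc[::16]):
            assert a == pytest.approx(accuracy_oracle(scores, truth, t))

    def test_all_identical_scores_flagged_non_separable(self):
        scores = [1.0] * 18
        truth = [True] * 9 + [False] * 9
        with pytest.warns(NonSeparableWarning):
            _, acc = sweep_thresholds(labeled(scores, truth), 50)
        assert acc.max() == 50.0

    def test_label_swap_complements_accuracy_without_ties(self, rng):
        scores = rng.permutation(np.linspace(0.0, 1.0, 20))  # no tied scores
        truth = rng.uniform(0, 1, size=20) > 0.4
        truth[0], truth[1] = True, False
        # evaluate strictly between scores so no fly sits on a threshold
        probe = (np.sort(scores)[:-1] + np.sort(scores)[1:]) / 2
        for t in probe:
            a = accuracy_oracle(scores, truth, t)
            a_swapped = accuracy_oracle(scores, ~truth, t)
            assert a + a_swapped == pytest.approx(100.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            labeled([1.0, 2.0], [True, True])


class TestBestThreshold:
    def test_single_maximum_index(self):
        thr = np.linspace(0, 1, 11)
        acc = np.zeros(11)
        acc[7] = 100.0
        assert best_threshold(thr, acc) == pytest.approx(thr[7])

    def test_plateau_midpoint(self):
        thr = np.linspace(0, 30, 31)
        acc = np.zeros(31)
        acc[10:21] = 90.0
        assert best_threshold(thr, acc) == pytest.approx(thr[15])

    def test_longest_of_two_plateaus_wins(self):
        thr = np.arange(30.0)
        acc = np.zeros(30)
        acc[2:5] = 80.0  # length 3
        acc[10:19] = 80.0  # length 9
        assert best_threshold(thr, acc) == pytest.approx(14.0)

    def test_plateaus_verified_by_run_length_oracle(self, rng):
        thr = np.arange(200.0)
        for _ in range(50):
            acc = rng.integers(0, 4, size=200).astype(float)
            got = best_threshold(thr, acc)
            # oracle: enumerate all maximal runs and pick the longest, earliest
            best = acc.max()
            runs = []
            i = 0
            while i < 200:
                if acc[i] == best:
                    j = i
                    while j < 200 and acc[j] == best:
                        j += 1
                    runs.append((i, j - 1))
                    i = j
                else:
                    i += 1
            start, end = max(runs, key=lambda r: r[1] - r[0])
            assert got == pytest.approx((thr[start] + thr[end]) / 2)


class TestLandscape:
    @pytest.fixture
    def separable_data(self, rng):
        # two metrics, both individually separable
        n = 20
        truth = np.array([True] * n + [False] * n)
        m1 = np.concatenate([rng.uniform(2.0, 3.0, n), rng.uniform(0.5, 1.0, n)])
        m2 = np.concatenate([rng.uniform(1.0, 2.0, n), rng.uniform(-0.5, 0.3, n)])
        return m1, m2, truth

    def test_endpoint_columns_equal_single_metric_sweeps(self, separable_data):
        m1, m2, truth = separable_data
        grid = np.array([0.0, 0.5, 1.0])
        land = weight_threshold_landscape(m1, m2, truth, grid, n_thresholds=200)
        ids = np.arange(len(truth))
        n1 = combine_scores(m1, m2, 1.0, land.norm_ranges["max5_ratio"],
                            land.norm_ranges["skewness"])
        _, acc1 = sweep_thresholds(LabeledScores(ids, n1, truth), 200)
        assert np.array_equal(land.accuracy[2], acc1)
        n0 = combine_scores(m1, m2, 0.0, land.norm_ranges["max5_ratio"],
                            land.norm_ranges["skewness"])
        _, acc0 = sweep_thresholds(LabeledScores(ids, n0, truth), 200)
        assert np.array_equal(land.accuracy[0], acc0)

    def test_separable_classes_give_100_at_every_weight(self, separable_data):
        m1, m2, truth = separable_data
        land = weight_threshold_landscape(m1, m2, truth, n_thresholds=300)
        assert np.all(land.accuracy.max(axis=1) == 100.0)
        assert land.selected_accuracy == 100.0

    def test_matrix_shape(self, separable_data):
        m1, m2, truth = separable_data
        grid = np.linspace(0, 1, 11)
        land = weight_threshold_landscape(m1, m2, truth, grid, n_thresholds=123)
        assert land.accuracy.shape == (11, 123)
        assert land.thresholds.shape == (11, 123)

    def test_combination_never_below_single_metrics(self, rng):
        # noisy, overlapping classes: grid includes w=0 and w=1 so the
        # landscape maximum dominates each single metric by construction
        n = 30
        truth = np.array([True] * n + [False] * n)
        m1 = np.concatenate([rng.normal(2, 0.8, n), rng.normal(1, 0.8, n)])
        m2 = np.concatenate([rng.normal(1, 0.6, n), rng.normal(0.2, 0.6, n)])
        land = weight_threshold_landscape(m1, m2, truth, n_thresholds=400)
        single_best = max(land.accuracy[0].max(), land.accuracy[-1].max())
        assert land.accuracy.max() >= single_best

    def test_selected_threshold_between_class_extrema_when_separable(
        self, separable_data
    ):
        m1, m2, truth = separable_data
        land = weight_threshold_landscape(m1, m2, truth)
        w, thr = land.selected_w, land.selected_threshold
        scores = combine_scores(
            m1, m2, w, land.norm_ranges["max5_ratio"], land.norm_ranges["skewness"]
        )
        assert scores[~truth].max() < thr <= scores[truth].min()

    def test_degenerate_metric_range_names_metric(self):
        truth = np.array([True, False])
        with pytest.raises(ValueError, match="max5_ratio"):
            weight_threshold_landscape(
                np.array([1.0, 1.0]), np.array([0.0, 1.0]), truth
            )

    def test_json_round_trip(self, separable_data, tmp_path):
        m1, m2, truth = separable_data
        land = weight_threshold_landscape(m1, m2, truth, n_thresholds=50)
        path = tmp_path / "cal.json"
        land.save(path)
        back = CalibrationLandscape.load(path)
        assert back.selected_w == land.selected_w
        assert back.selected_threshold == land.selected_threshold
        assert back.norm_ranges == land.norm_ranges
        assert np.allclose(back.accuracy, land.accuracy)


class TestOperatingPoint:
    def _landscape(self, acc, thr=None):
        n_w, n_t = acc.shape
        thresholds = (
            np.tile(np.arange(float(n_t)), (n_w, 1)) if thr is None else thr
        )
        return CalibrationLandscape(
            weights=np.linspace(0, 1, n_w),
            thresholds=thresholds,
            accuracy=acc,
            norm_ranges={"max5_ratio": (0, 1), "skewness": (0, 1)},
            metric_names=("max5_ratio", "skewness"),
        )

    def test_single_global_max_cell(self):
        acc = np.zeros((5, 10))
        acc[3, 6] = 99.0
        land = self._landscape(acc)
        w, thr = select_robust_operating_point(land)
        assert w == pytest.approx(land.weights[3])
        assert thr == pytest.approx(6.0)

    def test_widest_run_wins(self):
        acc = np.zeros((11, 40))
        w_a = 4  # weight 0.4: 12-cell run at max
        acc[w_a, 10:22] = 100.0
        w_b = 7  # weight 0.7: 5-cell run
        acc[w_b, 3:8] = 100.0
        land = self._landscape(acc)
        w, thr = select_robust_operating_point(land)
        assert w == pytest.approx(0.4)
        assert thr == pytest.approx((10 + 21) / 2)

    def test_uniform_landscape_ties_resolve_to_smallest_weight(self):
        acc = np.full((5, 21), 100.0)
        land = self._landscape(acc)
        w, thr = select_robust_operating_point(land)
        assert w == 0.0
        assert thr == pytest.approx(10.0)  # global threshold midpoint

    def test_default_weight_grid_is_percent_steps(self):
        assert len(DEFAULT_WEIGHT_GRID) == 101
        assert DEFAULT_WEIGHT_GRID[0] == 0.0 and DEFAULT_WEIGHT_GRID[-1] == 1.0
        assert np.allclose(np.diff(DEFAULT_WEIGHT_GRID), 0.01)
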