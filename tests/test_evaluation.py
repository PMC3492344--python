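import numpy as np
import pytest

from flyfluor import (
    IdentityCall,
    ImageStack,
    Label,
    accuracy_heatmap,
    accuracy_vs_image_count,
    discrimination_accuracy,
    select_images,
)
from flyfluor.calibration import weight_threshold_landscape
from flyfluor.evaluation import AccuracyCurve, ImageSelectMode, split_blocks
from flyfluor.io_data import Channel
from flyfluor.pipeline import measure_fly_metrics, scores_with_calibration
from flyfluor.synthetic_scenes import SceneConfig, make_scene


def call(fly_id, label):
    return IdentityCall(fly_id, label, 0.5, 0.1)


class TestDiscriminationAccuracy:
    def test_all_correct(self):
        truth = {i: Label.GFP if i < 9 else Label.NON_GFP for i in range(18)}
        calls = [call(i, truth[i]) for i in range(18)]
        assert discrimination_accuracy(calls, truth) == (100.0, 100.0, 100.0)

    def test_one_of_eighteen_wrong(self):
        truth = {i: Label.GFP if i < 9 else Label.NON_GFP for i in range(18)}
        calls = [call(i, truth[i]) for i in range(17)] + [call(17, Label.GFP)]
        overall, gfp, non = discrimination_accuracy(calls, truth)
        assert overall == pytest.approx(100 * 17 / 18)
        assert gfp == 100.0
        assert non == pytest.approx(100 * 8 / 9)

    def test_chance_level_for_independent_labels(self, rng):
        # calls independent of truth in a balanced group: expected 50%
        accs = []
        for s in range(200):
            truth = {i: Label.GFP if i < 9 else Label.NON_GFP for i in range(18)}
            perm = rng.permutation(18)
            calls = [
                call(int(i), Label.GFP if k < 9 else Label.NON_GFP)
                for k, i in enumerate(perm)
            ]
            accs.append(discrimination_accuracy(calls, truth)[0])
        assert np.mean(accs) == pytest.approx(50.0, abs=3.0)

    def test_missing_truth_raises(self):
        with pytest.raises(KeyError, match="99"):
            discrimination_accuracy([call(99, Label.GFP)], {0: Label.GFP})

    def test_relabeling_invariance(self, rng):
        truth = {i: Label.GFP if i % 3 else Label.NON_GFP for i in range(12)}
        calls = [
            call(i, Label.GFP if rng.uniform() < 0.5 else Label.NON_GFP)
            for i in range(12)
        ]
        base = discrimination_accuracy(calls, truth)
        mapping = {i: i + 100 for i in range(12)}
        calls2 = [
            IdentityCall(mapping[c.fly_id], c.label, c.score, c.margin) for c in calls
        ]
        truth2 = {mapping[i]: lab for i, lab in truth.items()}
        assert discrimination_accuracy(calls2, truth2) == base


def stack_with_blocks(pre, post):
    indices = list(pre) + list(post)
    frames = np.zeros((len(indices), 4, 4), dtype=np.uint8)
    return ImageStack(frames, Channel.FLUOR, frame_indices=indices)


class TestSelectImages:
    def test_two_images_bracket_the_experiment(self):
        stack = stack_with_blocks(range(200), range(1000, 1200))
        got = select_images(stack, 2, ImageSelectMode.ALTERNATE_START_END, split=1000)
        assert got == [0, 1000]

    def test_single_end_only_image(self):
        stack = stack_with_blocks(range(200), range(1000, 1200))
        assert select_images(stack, 1, ImageSelectMode.END_ONLY, split=1000) == [1000]

    def test_odd_count_favors_pre_block(self):
        stack = stack_with_blocks(range(200), range(1000, 1200))
        got = select_images(stack, 3, ImageSelectMode.ALTERNATE_START_END, split=1000)
        assert got == [0, 1000, 1]

    def test_alternation_continues_for_larger_counts(self):
        stack = stack_with_blocks(range(200), range(1000, 1200))
        got = select_images(stack, 6, ImageSelectMode.ALTERNATE_START_END, split=1000)
        assert got == [0, 1000, 1, 1001, 2, 1002]

    def test_end_only_in_order(self):
        stack = stack_with_blocks(range(200), range(1000, 1200))
        got = select_images(stack, 4, ImageSelectMode.END_ONLY, split=1000)
        assert got == [1000, 1001, 1002, 1003]

    def test_empty_pre_block_makes_modes_agree(self):
        stack = stack_with_blocks([], range(1000, 1200))
        for n in (1, 2, 5):
            assert select_images(
                stack, n, ImageSelectMode.ALTERNATE_START_END, split=1000
            ) == select_images(stack, n, ImageSelectMode.END_ONLY, split=1000)

    def test_requesting_too_many_images_raises(self):
        stack = stack_with_blocks(range(2), range(1000, 1002))
        with pytest.raises(ValueError):
            select_images(stack, 5, ImageSelectMode.ALTERNATE_START_END, split=1000)
        with pytest.raises(ValueError):
            select_images(stack, 3, ImageSelectMode.END_ONLY, split=1000)

    def test_default_split_halves_the_stack(self):
        stack = stack_with_blocks(range(10), [])
        pre, post = split_blocks(stack)
        assert pre == [0, 1, 2, 3, 4] and post == [5, 6, 7, 8, 9]


@pytest.fixture(scope="module")
def clean_calibration():
    """Calibration from homogeneous high-contrast scenes."""
    m1, m2, truth = [], [], []
    for s in range(3):
        for frac, is_gfp in ((1.0, True), (0.0, False)):
            cfg = SceneConfig(
                gfp_fraction=frac, seed=300 + 10 * s + int(frac), n_frames=8,
                noise_sd=2.0,
            )
            _, fluo, traj, _ = make_scene(cfg)
            table = measure_fly_metrics(fluo, traj)
            m1.extend(table["max5_ratio"])
            m2.extend(table["skewness"])
            truth.extend([is_gfp] * len(table))
    return weight_threshold_landscape(
        np.array(m1), np.array(m2), np.array(truth), n_thresholds=200,
        weight_grid=np.linspace(0, 1, 21),
    )


@pytest.fixture(scope="module")
def clean_scene():
    cfg = SceneConfig(seed=77, n_frames=8, noise_sd=2.0)
    _, fluo, traj, truth = make_scene(cfg)
    return fluo, traj, truth


class TestAccuracyVsImageCount:
    def test_clean_scene_is_perfect_at_every_count(
        self, clean_calibration, clean_scene
    ):
        fluo, traj, truth = clean_scene
        curve = accuracy_vs_image_count(
            fluo, traj, truth, clean_calibration, [1, 2, 4, 8],
            ImageSelectMode.ALTERNATE_START_END,
        )
        assert np.all(curve.overall == 100.0)
        assert np.all(curve.gfp == 100.0) and np.all(curve.non_gfp == 100.0)

    def test_full_stack_count_reproduces_all_images_result(
        self, clean_calibration, clean_scene
    ):
        fluo, traj, truth = clean_scene
        curve = accuracy_vs_image_count(
            fluo, traj, truth, clean_calibration, [len(fluo)],
            ImageSelectMode.ALTERNATE_START_END,
        )
        table = measure_fly_metrics(fluo, traj)
        scores = scores_with_calibration(table, clean_calibration)
        from flyfluor import classify_by_threshold

        calls = classify_by_threshold(scores, clean_calibration.selected_threshold)
        assert curve.overall[0] == discrimination_accuracy(calls, truth)[0]

    def test_one_row_per_requested_count(self, clean_calibration, clean_scene):
        fluo, traj, truth = clean_scene
        # the 8-frame stack halves into 4+4, so END_ONLY can draw up to 4
        counts = [1, 3, 4]
        curve = accuracy_vs_image_count(
            fluo, traj, truth, clean_calibration, counts,
            ImageSelectMode.END_ONLY,
        )
        assert list(curve.image_counts) == [1, 3, 4]
        assert len(curve.overall) == 3

    def test_counts_must_increase(self):
        with pytest.raises(ValueError):
            AccuracyCurve(
                np.array([2, 1]), np.zeros(2), np.zeros(2), np.zeros(2)
            )


class TestAccuracyHeatmap:
    def test_shape_and_plateau_on_clean_scene(self, clean_calibration, clean_scene):
        fluo, traj, truth = clean_scene
        counts = [1, 4]
        matrix = accuracy_heatmap(
            fluo, traj, truth, clean_calibration, counts,
            ImageSelectMode.ALTERNATE_START_END, prior_n_gfp=9,
        )
        assert matrix.shape == (2, len(clean_calibration.weights))
        # high-SNR prior-mode row at the larger count: broad 100% plateau
        assert (matrix[1] == 100.0).mean() > 0.5

    def test_weight_endpoints_match_single_metric_classification(
        self, clean_calibration, clean_scene
    ):
        from flyfluor import classify_by_prior_count
        from flyfluor.pipeline import scores_from_metrics

        fluo, traj, truth = clean_scene
        matrix = accuracy_heatmap(
            fluo, traj, truth, clean_calibration, [4],
            ImageSelectMode.ALTERNATE_START_END, prior_n_gfp=9,
        )
        frames = select_images(fluo, 4, ImageSelectMode.ALTERNATE_START_END)
        table = measure_fly_metrics(fluo, traj, frames)
        for col, w in ((0, 0.0), (-1, 1.0)):
            scores = scores_from_metrics(
                table, w, clean_calibration.norm_ranges
            )
            calls = classify_by_prior_count(scores, 9)
            assert matrix[0, col] == discrimination_accuracy(calls, truth)[0]
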