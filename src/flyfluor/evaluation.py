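"""Accuracy scoring and image-count analyses.

Discrimination accuracy is 100% minus the percentage of misassigned flies
(false positives + false negatives over the group). Because fluorescence
illumination is spatially inhomogeneous and flies move, accuracy improves
as metric measurements are averaged over more images; the analyses here
quantify that dependence, optionally jointly with the metric weighting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationLandscape, best_threshold
from .classification import classify_by_prior_count, classify_by_threshold
from .io_data import IdentityCall, ImageStack, Label, TrajectoryRecord
from .pipeline import measure_fly_metrics, scores_from_metrics


class ImageSelectMode(enum.Enum):
    #: alternate frames from the pre- and post-experiment imaging blocks,
    #: starting with (and, for odd counts, favoring) the pre block
    ALTERNATE_START_END = "alternate"
    #: use only frames from the post-experiment block, in order
    END_ONLY = "end-only"


@dataclass(frozen=True)
class AccuracyCurve:
    """Discrimination accuracy as a function of images averaged."""

    image_counts: np.ndarray
    overall: np.ndarray  # percent
    gfp: np.ndarray  # percent of true GFP flies called GFP
    non_gfp: np.ndarray  # percent of true non-GFP flies called non-GFP

    def __post_init__(self) -> None:
        counts = np.asarray(self.image_counts, dtype=int)
        object.__setattr__(self, "image_counts", counts)
        if len(counts) > 1 and np.any(np.diff(counts) <= 0):
            raise ValueError("image_counts must be strictly increasing")


def discrimination_accuracy(
    calls: Sequence[IdentityCall], truth: Mapping[int, Label]
) -> tuple[float, float, float]:
    """(overall, GFP-class, non-GFP-class) accuracy in percent.

    Class accuracies are the fraction of each true class called correctly;
    a class absent from the truth yields NaN for its entry.
    """
    missing = [c.fly_id for c in calls if c.fly_id not in truth]
    if missing:
        raise KeyError(f"no truth label for fly id(s) {missing}")
    n_fp = sum(
        1 for c in calls if c.label is Label.GFP and truth[c.fly_id] is Label.NON_GFP
    )
    n_fn = sum(
        1 for c in calls if c.label is Label.NON_GFP and truth[c.fly_id] is Label.GFP
    )
    n_gfp = sum(1 for c in calls if truth[c.fly_id] is Label.GFP)
    n_non = len(calls) - n_gfp
    overall = 100.0 * (1.0 - (n_fp + n_fn) / len(calls))
    gfp_acc = 100.0 * (n_gfp - n_fn) / n_gfp if n_gfp else float("nan")
    non_acc = 100.0 * (n_non - n_fp) / n_non if n_non else float("nan")
    return overall, gfp_acc, non_acc


def split_blocks(
    stack: ImageStack, split: int | None = None
) -> tuple[list[int], list[int]]:
    """Partition stack frame indices into (pre, post) experiment blocks.

    ``split`` is the first trajectory frame number of the post block; by
    default the stack is halved.
    """
    indices = [int(i) for i in stack.frame_indices]
    if split is None:
        half = len(indices) // 2
        return indices[:half], indices[half:]
    pre = [i for i in indices if i < split]
    post = [i for i in indices if i >= split]
    return pre, post


def select_images(
    stack: ImageStack,
    n: int,
    mode: ImageSelectMode,
    split: int | None = None,
) -> list[int]:
    """Pick ``n`` trajectory frame numbers from the stack's imaging blocks.

    ALTERNATE_START_END exploits fly movement between the two imaging
    bouts bracketing the experiment: frames are taken alternately from the
    front of the pre block and the front of the post block, pre first, with
    the extra frame going to the pre block when ``n`` is odd. END_ONLY takes
    the first ``n`` frames of the post block.
    """
    pre, post = split_blocks(stack, split)
    if mode is ImageSelectMode.END_ONLY:
        if n > len(post):
            raise ValueError(f"requested {n} images but post block has {len(post)}")
        return post[:n]
    if mode is ImageSelectMode.ALTERNATE_START_END:
        n_pre = min(len(pre), (n + 1) // 2)
        n_post = n - n_pre
        if n_post > len(post):
            n_post = len(post)
            n_pre = n - n_post
        if n_pre > len(pre) or n_post > len(post):
            raise ValueError(
                f"requested {n} images but blocks hold {len(pre)}+{len(post)}"
            )
        out: list[int] = []
        i = j = 0
        for k in range(n):
            take_pre = (k % 2 == 0 and i < n_pre) or j >= n_post
            if take_pre:
                out.append(pre[i])
                i += 1
            else:
                out.append(post[j])
                j += 1
        return out
    raise ValueError(f"unknown mode {mode!r}")


def _classify(
    scores: list[tuple[int, float]],
    landscape: CalibrationLandscape,
    prior_n_gfp: int | None,
    threshold: float | None = None,
) -> list[IdentityCall]:
    if prior_n_gfp is not None:
        return classify_by_prior_count(scores, prior_n_gfp)
    thr = landscape.selected_threshold if threshold is None else threshold
    return classify_by_threshold(scores, thr)


def accuracy_vs_image_count(
    fluo: ImageStack,
    trajectories: Sequence[TrajectoryRecord],
    truth: Mapping[int, Label],
    landscape: CalibrationLandscape,
    counts: Sequence[int],
    mode: ImageSelectMode = ImageSelectMode.ALTERNATE_START_END,
    prior_n_gfp: int | None = None,
    split: int | None = None,
    roi_params: Mapping[str, float] | None = None,
) -> AccuracyCurve:
    """Accuracy at the calibrated operating point for each image count.

    The calibration is fixed beforehand; for each requested count the
    selected images are averaged into fresh metric measurements, combined at
    the calibrated weight, and classified by threshold or prior count.
    """
    rp = dict(roi_params or landscape.params.get("roi", {}))
    overall, gfp, non = [], [], []
    for n in counts:
        frames = select_images(fluo, int(n), mode, split)
        table = measure_fly_metrics(fluo, trajectories, frames, **rp)
        scores = scores_from_metrics(
            table, landscape.selected_w, landscape.norm_ranges, landscape.metric_names
        )
        calls = _classify(scores, landscape, prior_n_gfp)
        o, g, ng = discrimination_accuracy(calls, truth)
        overall.append(o)
        gfp.append(g)
        non.append(ng)
    return AccuracyCurve(
        np.asarray(counts), np.asarray(overall), np.asarray(gfp), np.asarray(non)
    )


def accuracy_heatmap(
    fluo: ImageStack,
    trajectories: Sequence[TrajectoryRecord],
    truth: Mapping[int, Label],
    landscape: CalibrationLandscape,
    counts: Sequence[int],
    mode: ImageSelectMode = ImageSelectMode.ALTERNATE_START_END,
    prior_n_gfp: int | None = None,
    split: int | None = None,
    roi_params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Accuracy matrix over (image count, metric weight).

    With ``prior_n_gfp`` set, every grid cell uses the prior-count rule.
    Otherwise each weight is classified at its own best calibration
    threshold (the plateau midpoint of that weight's calibration sweep), so
    the landscape must carry its accuracy matrix.
    """
    rp = dict(roi_params or landscape.params.get("roi", {}))
    weights = landscape.weights
    if prior_n_gfp is None and np.isnan(landscape.accuracy).all():
        raise ValueError(
            "threshold-mode heatmap needs a landscape with its accuracy matrix"
        )
    out = np.empty((len(counts), len(weights)))
    for i, n in enumerate(counts):
        frames = select_images(fluo, int(n), mode, split)
        table = measure_fly_metrics(fluo, trajectories, frames, **rp)
        for j, w in enumerate(weights):
            scores = scores_from_metrics(
                table, float(w), landscape.norm_ranges, landscape.metric_names
            )
            if prior_n_gfp is not None:
                calls = classify_by_prior_count(scores, prior_n_gfp)
            else:
                thr = best_threshold(landscape.thresholds[j], landscape.accuracy[j])
                calls = classify_by_threshold(scores, thr)
            out[i, j] = discrimination_accuracy(calls, truth)[0]
    return out
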