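"""End-to-end study protocols on synthetic scenes.

These functions bundle the full workflow — homogeneous-group calibration,
heterogeneous-group testing, and image-count analyses — into the two study
conditions the package documents:

* the *high-contrast* condition (:class:`SceneConfig` defaults): thoracic
  GFP at twice the abdominal autofluorescence, read noise far below both;
* the *low-SNR* condition (:func:`noisy_config`): per-pixel noise as large
  as the abdominal amplitude, eye autofluorescence on.

They are the package's reproducible benchmark drivers; both the test suite
and the results-reproduction script call them.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Sequence

import numpy as np

from .calibration import CalibrationLandscape, weight_threshold_landscape
from .classification import classify_by_prior_count, classify_by_threshold
from .evaluation import (
    ImageSelectMode,
    accuracy_vs_image_count,
    discrimination_accuracy,
)
from .io_data import Label
from .pipeline import measure_fly_metrics, scores_with_calibration
from .synthetic_scenes import SceneConfig, make_scene


def calibrate_on_homogeneous_scenes(
    base_config: SceneConfig,
    n_scenes_per_class: int,
    seed: int,
    n_thresholds: int = 1000,
) -> CalibrationLandscape:
    """Calibrate from equally many all-GFP and all-non-GFP scenes.

    Scene seeds are derived deterministically from ``seed``. Metrics are
    measured over every image of each scene, pooled across scenes, and swept
    over the default weight grid.
    """
    m1, m2, truth = [], [], []
    for k in range(n_scenes_per_class):
        for frac, is_gfp in ((1.0, True), (0.0, False)):
            cfg = replace(
                base_config, gfp_fraction=frac, seed=seed + 2 * k + int(is_gfp)
            )
            _, fluo, trajectories, _ = make_scene(cfg)
            table = measure_fly_metrics(fluo, trajectories)
            m1.extend(table["max5_ratio"])
            m2.extend(table["skewness"])
            truth.extend([is_gfp] * len(table))
    return weight_threshold_landscape(
        np.asarray(m1), np.asarray(m2), np.asarray(truth), n_thresholds=n_thresholds
    )


def score_heterogeneous_scene(
    landscape: CalibrationLandscape,
    config: SceneConfig,
    frames: Sequence[int] | None = None,
) -> tuple[list[tuple[int, float]], dict[int, Label]]:
    """Generate one mixed scene and return (combined scores, truth)."""
    _, fluo, trajectories, truth = make_scene(config)
    table = measure_fly_metrics(fluo, trajectories, frames)
    return scores_with_calibration(table, landscape), truth


def heterogeneous_accuracy(
    landscape: CalibrationLandscape,
    base_config: SceneConfig,
    n_scenes: int,
    seed: int,
) -> dict[str, float]:
    """Mean threshold-mode and prior-count accuracy over fresh mixed scenes.

    Each scene holds ``base_config.n_flies`` flies at the configured GFP
    fraction; all images are used.
    """
    thr_acc, prior_acc = [], []
    for k in range(n_scenes):
        cfg = replace(base_config, seed=seed + k)
        scores, truth = score_heterogeneous_scene(landscape, cfg)
        calls_thr = classify_by_threshold(scores, landscape.selected_threshold)
        calls_prior = classify_by_prior_count(scores, cfg.n_gfp)
        thr_acc.append(discrimination_accuracy(calls_thr, truth)[0])
        prior_acc.append(discrimination_accuracy(calls_prior, truth)[0])
    return {
        "threshold_accuracy_pct": float(np.mean(thr_acc)),
        "prior_count_accuracy_pct": float(np.mean(prior_acc)),
        "n_flies_tested": n_scenes * base_config.n_flies,
    }


def image_count_replicates(
    landscape: CalibrationLandscape,
    base_config: SceneConfig,
    counts: Sequence[int],
    n_replicates: int,
    seed: int,
    mode: ImageSelectMode = ImageSelectMode.ALTERNATE_START_END,
) -> dict[str, np.ndarray]:
    """Seed-averaged accuracy-vs-image-count curves, both decision rules.

    Returns the mean curves over ``n_replicates`` fresh mixed scenes, as
    ``{"counts", "prior", "threshold"}`` arrays.
    """
    prior = np.zeros(len(counts))
    thr = np.zeros(len(counts))
    for k in range(n_replicates):
        cfg = replace(base_config, seed=seed + k)
        _, fluo, trajectories, truth = make_scene(cfg)
        prior += accuracy_vs_image_count(
            fluo, trajectories, truth, landscape, counts, mode,
            prior_n_gfp=cfg.n_gfp,
        ).overall
        thr += accuracy_vs_image_count(
            fluo, trajectories, truth, landscape, counts, mode
        ).overall
    return {
        "counts": np.asarray(counts),
        "prior": prior / n_replicates,
        "threshold": thr / n_replicates,
    }
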