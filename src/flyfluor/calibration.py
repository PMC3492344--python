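"""Operating-point calibration from homogeneous-group data.

Flies from genetically homogeneous groups (all-GFP or all-non-GFP) have
known labels, so their metric values can be swept against a grid of
candidate decision thresholds and metric weightings. For each weighting the
two normalized metrics are combined, 1000 thresholds spanning the observed
combined-score range are scored, and the resulting accuracy landscape over
(weight, threshold) is searched for its widest maximum-accuracy plateau.
The plateau center is the robust operating point: small drifts in
fluorescence level move scores less than half a plateau width before any
fly crosses the boundary.

The decision rule is ``score >= threshold -> GFP``; equality goes to the
GFP side so the rule is deterministic (equality is measure-zero for
continuous scores).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import NonSeparableWarning
from .io_data import Label

__version__ = "0.1.0"

DEFAULT_N_THRESHOLDS = 1000
DEFAULT_WEIGHT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class LabeledScores:
    """Per-fly scores with ground-truth labels from homogeneous groups."""

    fly_ids: np.ndarray
    scores: np.ndarray
    truth: np.ndarray  # boolean, True = GFP

    def __post_init__(self) -> None:
        object.__setattr__(self, "fly_ids", np.asarray(self.fly_ids, dtype=int))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "truth", np.asarray(self.truth, dtype=bool))
        if not (len(self.fly_ids) == len(self.scores) == len(self.truth)):
            raise ValueError("fly_ids, scores, truth must be equal-length")
        if not (self.truth.any() and (~self.truth).any()):
            raise ValueError("calibration requires at least one fly of each class")

    @classmethod
    def from_entries(
        cls, entries: Sequence[tuple[int, float, Label]]
    ) -> "LabeledScores":
        ids, scores, truth = zip(*entries)
        return cls(
            np.array(ids), np.array(scores),
            np.array([t is Label.GFP for t in truth]),
        )


def sweep_thresholds(
    scores: LabeledScores, n_thresholds: int = DEFAULT_N_THRESHOLDS
) -> tuple[np.ndarray, np.ndarray]:
    """Score ``n_thresholds`` evenly spaced thresholds over the observed
    score range.

    Returns (thresholds, accuracy) where ``accuracy[i]`` is the percent of
    flies classified correctly by ``score >= thresholds[i] -> GFP``.
    All-identical scores produce a degenerate sweep (every threshold equal,
    every fly called GFP) flagged with :class:`NonSeparableWarning`.
    """
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    lo, hi = float(scores.scores.min()), float(scores.scores.max())
    thresholds = np.linspace(lo, hi, n_thresholds)
    if lo == hi:
        warnings.warn(
            "all calibration scores identical; classes are non-separable",
            NonSeparableWarning,
            stacklevel=2,
        )
    pred = scores.scores[None, :] >= thresholds[:, None]
    accuracy = 100.0 * (pred == scores.truth[None, :]).mean(axis=1)
    return thresholds, accuracy


def _max_plateau(accuracy: np.ndarray) -> tuple[int, int]:
    """(start, end) inclusive indices of the longest contiguous run attaining
    the maximum; earliest run wins ties."""
    best = accuracy.max()
    at_max = accuracy == best
    run_start = best_start = best_end = -1
    best_len = 0
    for i, hit in enumerate(at_max):
        if hit:
            if run_start < 0:
                run_start = i
            if i - run_start + 1 > best_len:
                best_len = i - run_start + 1
                best_start, best_end = run_start, i
        else:
            run_start = -1
    return best_start, best_end


def best_threshold(thresholds: np.ndarray, accuracy: np.ndarray) -> float:
    """Midpoint of the longest contiguous maximum-accuracy threshold run."""
    thresholds = np.asarray(thresholds, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if len(thresholds) != len(accuracy) or len(thresholds) == 0:
        raise ValueError("thresholds and accuracy must be equal-length and non-empty")
    start, end = _max_plateau(accuracy)
    return float((thresholds[start] + thresholds[end]) / 2.0)


@dataclass
class CalibrationLandscape:
    """Accuracy over a (weight, threshold) grid plus the selected robust
    operating point and everything needed to re-apply it.

    ``thresholds[i]`` is the threshold grid swept for ``weights[i]`` (each
    weight has its own combined-score range); ``accuracy[i, j]`` is percent
    correct at (weights[i], thresholds[i, j]). ``norm_ranges`` are the
    min-max normalization ranges of the two metrics, frozen from the
    calibration cohort.
    """

    weights: np.ndarray
    thresholds: np.ndarray  # (n_weights, n_thresholds)
    accuracy: np.ndarray  # (n_weights, n_thresholds), percent
    norm_ranges: dict[str, tuple[float, float]]
    metric_names: tuple[str, str]
    selected_w: float = float("nan")
    selected_threshold: float = float("nan")
    selected_accuracy: float = float("nan")
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path, include_matrix: bool = True) -> None:
        doc = {
            "software_version": __version__,
            "metric_names": list(self.metric_names),
            "norm_ranges": {k: list(v) for k, v in self.norm_ranges.items()},
            "weights": self.weights.tolist(),
            "n_thresholds": int(self.thresholds.shape[1]),
            "selected": {
                "w": self.selected_w,
                "threshold": self.selected_threshold,
                "accuracy": self.selected_accuracy,
            },
            "params": self.params,
        }
        if include_matrix:
            doc["thresholds"] = self.thresholds.tolist()
            doc["accuracy"] = self.accuracy.tolist()
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationLandscape":
        doc = json.loads(Path(path).read_text())
        n_thr = doc["n_thresholds"]
        weights = np.asarray(doc["weights"], dtype=float)
        thresholds = np.asarray(
            doc.get("thresholds", np.full((len(weights), n_thr), np.nan)), dtype=float
        )
        accuracy = np.asarray(
            doc.get("accuracy", np.full((len(weights), n_thr), np.nan)), dtype=float
        )
        return cls(
            weights=weights,
            thresholds=thresholds,
            accuracy=accuracy,
            norm_ranges={k: tuple(v) for k, v in doc["norm_ranges"].items()},
            metric_names=tuple(doc["metric_names"]),
            selected_w=doc["selected"]["w"],
            selected_threshold=doc["selected"]["threshold"],
            selected_accuracy=doc["selected"]["accuracy"],
            params=doc.get("params", {}),
        )


def combine_scores(
    m1: np.ndarray,
    m2: np.ndarray,
    w: float,
    norm1: tuple[float, float],
    norm2: tuple[float, float],
) -> np.ndarray:
    """Vectorized weighted combination of two normalized metric columns."""
    (lo1, hi1), (lo2, hi2) = norm1, norm2
    if not (hi1 > lo1 and hi2 > lo2):
        raise ValueError("degenerate normalization range")
    n1 = np.clip((np.asarray(m1, dtype=float) - lo1) / (hi1 - lo1), 0.0, 1.0)
    n2 = np.clip((np.asarray(m2, dtype=float) - lo2) / (hi2 - lo2), 0.0, 1.0)
    return w * n1 + (1.0 - w) * n2


def weight_threshold_landscape(
    m1_values: np.ndarray,
    m2_values: np.ndarray,
    truth: np.ndarray,
    weight_grid: np.ndarray | None = None,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    metric_names: tuple[str, str] = ("max5_ratio", "skewness"),
    params: dict | None = None,
) -> CalibrationLandscape:
    """Sweep the full (weight, threshold) grid on labeled calibration data.

    Normalization ranges are fixed from this data's observed min/max per
    metric and persisted with the landscape so later classification is
    reproducible. The robust operating point is selected immediately.
    """
    m1 = np.asarray(m1_values, dtype=float)
    m2 = np.asarray(m2_values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if not (len(m1) == len(m2) == len(truth)):
        raise ValueError("metric vectors and truth must be aligned")
    weight_grid = (
        DEFAULT_WEIGHT_GRID.copy() if weight_grid is None
        else np.asarray(weight_grid, dtype=float)
    )
    if np.any((weight_grid < 0) | (weight_grid > 1)):
        raise ValueError("weights must lie in [0, 1]")
    norm_ranges = {}
    for name, vals in zip(metric_names, (m1, m2)):
        lo, hi = float(vals.min()), float(vals.max())
        if not hi > lo:
            raise ValueError(f"degenerate normalization range for metric '{name}'")
        norm_ranges[name] = (lo, hi)

    fly_ids = np.arange(len(truth))
    thresholds = np.empty((len(weight_grid), n_thresholds))
    accuracy = np.empty_like(thresholds)
    for i, w in enumerate(weight_grid):
        combined = combine_scores(
            m1, m2, float(w), norm_ranges[metric_names[0]], norm_ranges[metric_names[1]]
        )
        thr, acc = sweep_thresholds(LabeledScores(fly_ids, combined, truth), n_thresholds)
        thresholds[i] = thr
        accuracy[i] = acc

    landscape = CalibrationLandscape(
        weights=weight_grid,
        thresholds=thresholds,
        accuracy=accuracy,
        norm_ranges=norm_ranges,
        metric_names=metric_names,
        params=params or {},
    )
    w_star, thr_star = select_robust_operating_point(landscape)
    landscape.selected_w = w_star
    landscape.selected_threshold = thr_star
    landscape.selected_accuracy = float(accuracy.max())
    return landscape


def select_robust_operating_point(
    landscape: CalibrationLandscape,
) -> tuple[float, float]:
    """Pick (w*, theta*) at the widest maximum-accuracy plateau.

    Among weights attaining the landscape's global maximum accuracy, the one
    whose longest contiguous threshold run at that maximum is largest wins
    (ties go to the smaller weight); theta* is that run's midpoint.
    """
    global_max = landscape.accuracy.max()
    best_w_idx = -1
    best_len = -1
    best_span: tuple[int, int] = (0, 0)
    for i in range(len(landscape.weights)):
        row = landscape.accuracy[i]
        if row.max() < global_max:
            continue
        start, end = _max_plateau(row)
        length = end - start + 1
        if length > best_len:
            best_len = length
            best_w_idx = i
            best_span = (start, end)
    start, end = best_span
    thr = landscape.thresholds[best_w_idx]
    return (
        float(landscape.weights[best_w_idx]),
        float((thr[start] + thr[end]) / 2.0),
    )
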