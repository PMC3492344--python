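"""Glue between image stacks, trajectories, and per-fly metric tables.

This module holds no science of its own: it indexes trajectories, walks the
selected fluorescence images, extracts ROI pixel samples, and hands them to
the metric functions with the correct averaging mode.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import metrics as _metrics
from .calibration import CalibrationLandscape, combine_scores
from .io_data import ImageStack, TrajectoryRecord
from .roi_geometry import extract_pixels, split_roi, total_roi

DEFAULT_ROI_SCALE = 1.2
DEFAULT_FRONT_FRACTION = 0.5


def index_trajectories(
    records: Sequence[TrajectoryRecord],
) -> dict[int, dict[int, TrajectoryRecord]]:
    """Map frame -> fly_id -> record."""
    out: dict[int, dict[int, TrajectoryRecord]] = {}
    for rec in records:
        out.setdefault(rec.frame, {})[rec.fly_id] = rec
    return out


def measure_fly_metrics(
    fluo: ImageStack,
    trajectories: Sequence[TrajectoryRecord],
    frames: Sequence[int] | None = None,
    length_scale: float = DEFAULT_ROI_SCALE,
    width_scale: float = DEFAULT_ROI_SCALE,
    front_fraction: float = DEFAULT_FRONT_FRACTION,
) -> pd.DataFrame:
    """Compute Max 5% Ratio and Skewness per fly over the selected images.

    ``frames`` are trajectory frame numbers (values of ``fluo.frame_indices``);
    by default every stack frame is used. Every fly must be tracked in every
    selected frame. Returns a DataFrame with columns
    ``fly_id, max5_ratio, skewness, n_images``.
    """
    if frames is None:
        frames = list(fluo.frame_indices)
    frame_to_page = {int(f): k for k, f in enumerate(fluo.frame_indices)}
    missing = [f for f in frames if int(f) not in frame_to_page]
    if missing:
        raise KeyError(f"frames {missing} not present in the image stack")
    by_frame = index_trajectories(trajectories)

    fly_ids = sorted({r.fly_id for r in trajectories})
    front: dict[int, list] = {f: [] for f in fly_ids}
    rear: dict[int, list] = {f: [] for f in fly_ids}
    skew: dict[int, list[float]] = {f: [] for f in fly_ids}
    for frame in frames:
        frame = int(frame)
        image = fluo.frames[frame_to_page[frame]]
        poses = by_frame.get(frame, {})
        for fly_id in fly_ids:
            if fly_id not in poses:
                raise KeyError(f"fly {fly_id} has no pose at frame {frame}")
            roi = total_roi(poses[fly_id], length_scale, width_scale)
            f_roi, r_roi = split_roi(roi, front_fraction)
            src = (fly_id, frame)
            total_sample = extract_pixels(image, roi, src)
            front[fly_id].append(extract_pixels(image, f_roi, src))
            rear[fly_id].append(extract_pixels(image, r_roi, src))
            skew[fly_id].append(_metrics.skewness(total_sample))

    rows = [
        {
            "fly_id": fly_id,
            "max5_ratio": _metrics.max5_ratio(front[fly_id], rear[fly_id]),
            "skewness": _metrics.average_metric_over_images(skew[fly_id]),
            "n_images": len(frames),
        }
        for fly_id in fly_ids
    ]
    return pd.DataFrame(rows)


def scores_from_metrics(
    table: pd.DataFrame,
    w: float,
    norm_ranges: Mapping[str, tuple[float, float]],
    metric_names: tuple[str, str] = ("max5_ratio", "skewness"),
) -> list[tuple[int, float]]:
    """Combine a per-fly metric table into (fly_id, combined score) pairs."""
    m1, m2 = metric_names
    combined = combine_scores(
        table[m1].to_numpy(), table[m2].to_numpy(), w,
        tuple(norm_ranges[m1]), tuple(norm_ranges[m2]),
    )
    return list(zip(table["fly_id"].astype(int), map(float, combined)))


def scores_with_calibration(
    table: pd.DataFrame, landscape: CalibrationLandscape, w: float | None = None
) -> list[tuple[int, float]]:
    """Combined scores at the landscape's selected weight (or an override)."""
    return scores_from_metrics(
        table,
        landscape.selected_w if w is None else w,
        landscape.norm_ranges,
        landscape.metric_names,
    )
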