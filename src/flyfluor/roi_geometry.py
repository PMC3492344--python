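"""Oriented per-fly regions of interest and pixel extraction.

Each tracked fly gets a rectangular Total ROI centered on its centroid and
aligned with its body axis, sized as a multiple of the fitted body-ellipse
semi-axes. The Total ROI is split perpendicular to the body axis into a
head-ward Front ROI (head + thorax, where GFP fluorescence concentrates)
and a Rear ROI (abdomen, dominated by cuticular autofluorescence).

Pixel membership uses pixel centers with a half-open rule along both local
axes (low edge in, high edge out, tolerance 1e-9), so the rasterized Front
and Rear ROIs tile the Total ROI exactly: no pixel is lost at the split
plane and none is counted twice.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptySampleError
from .io_data import TrajectoryRecord

EDGE_TOL = 1e-9


class RoiPart(enum.Enum):
    TOTAL = "total"
    FRONT = "front"
    REAR = "rear"


@dataclass(frozen=True)
class OrientedRoi:
    """A rectangle centered at ``center``, rotated by ``theta``.

    ``half_length`` extends along the body axis (the +theta direction is
    head-ward), ``half_width`` across it.
    """

    center: tuple[float, float]
    theta: float
    half_length: float
    half_width: float
    part: RoiPart

    def __post_init__(self) -> None:
        if not (self.half_length > 0 and self.half_width > 0):
            raise ValueError("ROI half-extents must be positive")

    @property
    def corners(self) -> np.ndarray:
        """4x2 array of corner (x, y), counterclockwise from the rear-right."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        axis = np.array([c, s])
        perp = np.array([-s, c])
        cx = np.asarray(self.center, dtype=float)
        hl, hw = self.half_length, self.half_width
        return np.array(
            [
                cx - hl * axis - hw * perp,
                cx + hl * axis - hw * perp,
                cx + hl * axis + hw * perp,
                cx - hl * axis + hw * perp,
            ]
        )


@dataclass(frozen=True)
class PixelSample:
    """Intensity values extracted from one ROI in one image."""

    values: np.ndarray
    source: tuple[int, int, RoiPart] | None = None  # (fly_id, frame, part)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        object.__setattr__(self, "values", vals)
        if vals.size < 1:
            raise EmptySampleError(f"empty pixel sample (source={self.source})")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"pixel values must be finite and non-negative (source={self.source})")

    @property
    def n(self) -> int:
        return int(self.values.size)


def total_roi(
    record: TrajectoryRecord, length_scale: float = 1.2, width_scale: float = 1.2
) -> OrientedRoi:
    """Build the Total ROI for one pose.

    The box is centered on the centroid and aligned with the body axis;
    ``half_length = length_scale * a`` and ``half_width = width_scale * b``.
    The default 1.2 encloses the fitted body ellipse with a small margin.
    """
    if not (length_scale > 0 and width_scale > 0):
        raise ValueError("ROI scales must be positive")
    return OrientedRoi(
        center=(record.x, record.y),
        theta=record.theta,
        half_length=length_scale * record.a,
        half_width=width_scale * record.b,
        part=RoiPart.TOTAL,
    )


def split_roi(
    total: OrientedRoi, front_fraction: float = 0.5
) -> tuple[OrientedRoi, OrientedRoi]:
    """Split a Total ROI into (front, rear) perpendicular to the body axis.

    ``front_fraction`` is the share of the box length assigned to the
    head-ward Front ROI (default 0.5: split plane through the box center).
    Width is shared and the two halves tile the total exactly.
    """
    if total.part is not RoiPart.TOTAL:
        raise ValueError("split_roi expects a TOTAL ROI")
    if not (0 < front_fraction < 1):
        raise ValueError("front_fraction must be in (0, 1)")
    c, s = math.cos(total.theta), math.sin(total.theta)
    hl = total.half_length
    hl_front = front_fraction * hl
    hl_rear = (1.0 - front_fraction) * hl
    # centers offset along the axis so that front spans [split, +hl] and
    # rear spans [-hl, split] in the total's local axis coordinate
    front_center = (
        total.center[0] + (hl - hl_front) * c,
        total.center[1] + (hl - hl_front) * s,
    )
    rear_center = (
        total.center[0] - (hl - hl_rear) * c,
        total.center[1] - (hl - hl_rear) * s,
    )
    front = OrientedRoi(front_center, total.theta, hl_front, total.half_width, RoiPart.FRONT)
    rear = OrientedRoi(rear_center, total.theta, hl_rear, total.half_width, RoiPart.REAR)
    return front, rear


def _membership(
    px: np.ndarray, py: np.ndarray, roi: OrientedRoi
) -> np.ndarray:
    """Half-open pixel-center membership test, vectorized over coordinates."""
    c, s = math.cos(roi.theta), math.sin(roi.theta)
    dx = px - roi.center[0]
    dy = py - roi.center[1]
    u = dx * c + dy * s  # along body axis
    v = -dx * s + dy * c  # across
    return (
        (u >= -roi.half_length - EDGE_TOL)
        & (u < roi.half_length - EDGE_TOL)
        & (v >= -roi.half_width - EDGE_TOL)
        & (v < roi.half_width - EDGE_TOL)
    )


def roi_pixel_coords(roi: OrientedRoi, shape: tuple[int, int]) -> np.ndarray:
    """(x, y) integer coordinates of the pixels inside ``roi`` within an
    image of the given (height, width), in row-major order."""
    h, w = shape
    xs = roi.corners[:, 0]
    ys = roi.corners[:, 1]
    x0 = max(0, math.floor(xs.min()))
    x1 = min(w - 1, math.ceil(xs.max()))
    y0 = max(0, math.floor(ys.min()))
    y1 = min(h - 1, math.ceil(ys.max()))
    if x1 < x0 or y1 < y0:
        return np.empty((0, 2), dtype=int)
    px, py = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = _membership(px.astype(float), py.astype(float), roi)
    return np.column_stack([px[inside], py[inside]])


def extract_pixels(
    image: np.ndarray,
    roi: OrientedRoi,
    source: tuple[int, int] | None = None,
) -> PixelSample:
    """Extract the intensity values of every pixel whose center lies inside
    the oriented rectangle and inside the image bounds.

    ``source`` optionally carries (fly_id, frame) for error reporting and
    provenance. Raises :class:`EmptySampleError` when the ROI lies entirely
    outside the image.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    coords = roi_pixel_coords(roi, image.shape)
    if coords.shape[0] == 0:
        where = f" (fly_id, frame)={source}" if source else ""
        raise EmptySampleError(f"ROI {roi.part.value} yields no pixels{where}")
    values = image[coords[:, 1], coords[:, 0]]
    src = (source[0], source[1], roi.part) if source else None
    return PixelSample(values=values, source=src)
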