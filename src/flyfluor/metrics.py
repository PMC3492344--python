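"""Per-fly, dimensionless fluorescence discrimination metrics.

Two averaging modes exist when a fly was imaged more than once:

* ``RATIO_OF_AVERAGES`` — the numerator and denominator statistics are each
  averaged over images first and divided once (used for the Max 5% Ratio,
  which normalizes thoracic GFP signal by abdominal autofluorescence);
* ``AVERAGE_OF_VALUES`` — the metric is computed per image and the values
  are averaged (used for Skewness of the Total-ROI intensity histogram).

Both metrics are invariant to uniform rescaling of pixel values, which is
what makes them portable across illumination intensities and cameras.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDenominatorError, DegenerateSampleError
from .roi_geometry import PixelSample, RoiPart


class AveragingMode(enum.Enum):
    RATIO_OF_AVERAGES = "ratio_of_averages"
    AVERAGE_OF_VALUES = "average_of_values"


@dataclass(frozen=True)
class MetricDefinition:
    name: str
    averaging_mode: AveragingMode
    requires: frozenset[RoiPart]


@dataclass(frozen=True)
class MetricValue:
    fly_id: int
    metric: str
    value: float
    n_images: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite metric value for fly {self.fly_id}")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def top_fraction_mean(sample: PixelSample, fraction: float) -> float:
    """Mean of the brightest ``fraction`` of pixel values.

    The pixel count used is ``k = max(1, ceil(fraction * n))``, so the
    statistic is defined for every non-empty sample.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    values = sample.values
    k = max(1, math.ceil(fraction * values.size))
    top = np.partition(values.astype(float), values.size - k)[values.size - k:]
    return float(top.mean())


def _ratio_of_averages(
    front_samples: Sequence[PixelSample],
    rear_samples: Sequence[PixelSample],
    fraction: float,
) -> float:
    if len(front_samples) != len(rear_samples) or not front_samples:
        raise ValueError("front and rear sample lists must be equal-length and non-empty")
    num = float(np.mean([top_fraction_mean(s, fraction) for s in front_samples]))
    den = float(np.mean([top_fraction_mean(s, fraction) for s in rear_samples]))
    if den == 0:
        src = rear_samples[0].source
        fly = src[0] if src else "?"
        raise DegenerateDenominatorError(
            f"rear-ROI average is zero for fly {fly}; ratio undefined"
        )
    return num / den


def max5_ratio(
    front_samples: Sequence[PixelSample], rear_samples: Sequence[PixelSample]
) -> float:
    """Time-averaged mean of the brightest 5% of Front-ROI pixels divided by
    the time-averaged mean of the brightest 5% of Rear-ROI pixels."""
    return _ratio_of_averages(front_samples, rear_samples, 0.05)


def single_max_ratio(
    front_samples: Sequence[PixelSample], rear_samples: Sequence[PixelSample]
) -> float:
    """As :func:`max5_ratio` with the single maximum pixel per image.

    Performs like the Max 5% Ratio on clean data but is less robust to
    pixel noise, so it is shipped for comparison rather than as a default.
    """
    return _ratio_of_averages(front_samples, rear_samples, 1e-12)


def skewness(sample: PixelSample) -> float:
    """Biased sample skewness s = m3 / m2^(3/2) of one pixel sample.

    Central moments use divisor n. A fly with a compact bright thoracic blob
    on a dim body yields a strongly right-skewed Total-ROI histogram.
    """
    values = np.asarray(sample.values, dtype=float)
    if values.size < 3:
        raise DegenerateSampleError("skewness requires at least 3 pixels")
    if np.all(values == values[0]):
        raise DegenerateSampleError(
            f"zero-variance pixel sample (source={sample.source}); skewness undefined"
        )
    return float(stats.skew(values, bias=True))


def average_metric_over_images(per_image_values: Sequence[float]) -> float:
    """Arithmetic mean of per-image metric values (AVERAGE_OF_VALUES mode)."""
    if len(per_image_values) == 0:
        raise ValueError("need at least one per-image value")
    return float(np.mean(per_image_values))


def combined_score(
    v1: float,
    v2: float,
    w: float,
    norm1: tuple[float, float],
    norm2: tuple[float, float],
) -> float:
    """Weighted combination ``w*n1 + (1-w)*n2`` of two min-max normalized
    metric values.

    Each value is mapped through ``clip((v - lo) / (hi - lo), 0, 1)`` using
    normalization ranges fixed at calibration time, so the two metrics'
    different natural scales contribute comparably. The result lies in [0, 1].
    """
    if not (0 <= w <= 1):
        raise ValueError("weight must be in [0, 1]")
    out = 0.0
    for weight, v, (lo, hi) in ((w, v1, norm1), (1.0 - w, v2, norm2)):
        if not hi > lo:
            raise ValueError(f"degenerate normalization range ({lo}, {hi})")
        out += weight * min(1.0, max(0.0, (v - lo) / (hi - lo)))
    return out


#: The shipped metric registry. Further metrics can be registered by adding
#: a MetricDefinition under a new unique name.
METRICS: dict[str, MetricDefinition] = {
    "max5_ratio": MetricDefinition(
        "max5_ratio", AveragingMode.RATIO_OF_AVERAGES,
        frozenset({RoiPart.FRONT, RoiPart.REAR}),
    ),
    "skewness": MetricDefinition(
        "skewness", AveragingMode.AVERAGE_OF_VALUES, frozenset({RoiPart.TOTAL}),
    ),
    "single_max_ratio": MetricDefinition(
        "single_max_ratio", AveragingMode.RATIO_OF_AVERAGES,
        frozenset({RoiPart.FRONT, RoiPart.REAR}),
    ),
}
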