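"""Dynamic double-threshold quantization to a black/gray/white image.

Infrared cabin frames are strongly bimodal: the illuminated face is bright
while the seat, ceiling and background are very dark.  Rather than a fixed
threshold, the pipeline derives thresholds from the intensity histogram of
the exact region being processed, so every frame, face band and candidate
eye patch gets its own adaptive levels.

The construction trims a configurable tail fraction (default 17%) of the
pixel population from each end of the histogram to obtain a robust intensity
range ``[left_value, right_value]``.  Its midpoint ``t`` is the plain
black/white threshold; splitting ``t`` toward each end gives the double
thresholds ``dt1 = avg(left_value, t)`` and ``dt2 = avg(t, right_value)``,
which carve the image into three levels::

    p(x) = 0    if x <  dt1      (black)
           127  if dt1 <= x <= dt2  (gray)
           255  if x >  dt2      (white)

All averages use integer floor division, since pixel values are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Box

#: Ternary pixel levels.
BLACK = 0
GRAY = 127
WHITE = 255

#: Default fraction of the pixel population trimmed from each histogram end.
DEFAULT_TAIL_FRACTION = 0.17


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram of an 8-bit region.

    ``counts[v]`` is the number of pixels with value ``v``; ``total`` is the
    number of pixels in the region the histogram was built from.
    """

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if int(counts.sum()) != self.total:
            raise ValueError("histogram total does not match its counts")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ThresholdSet:
    """The five histogram-derived levels governing quantization.

    Invariant: ``left_value <= dt1 <= t <= dt2 <= right_value``.
    """

    left_value: int
    right_value: int
    t: int
    dt1: int
    dt2: int
    tail_fraction: float = DEFAULT_TAIL_FRACTION

    def __post_init__(self) -> None:
        if not (
            0 <= self.left_value <= self.dt1 <= self.t
            <= self.dt2 <= self.right_value <= 255
        ):
            raise ValueError(f"threshold ordering violated: {self}")


def _check_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            f"expected a single-channel 2D image, got shape {image.shape}; "
            "multi-channel inputs are rejected (no silent conversion)"
        )
    if image.dtype != np.uint8:
        if image.dtype.kind not in "iu" or image.min() < 0 or image.max() > 255:
            raise ValueError("image values must be 8-bit integers in [0, 255]")
        image = image.astype(np.uint8)
    return image


def _region_view(image: np.ndarray, region: Box | None) -> np.ndarray:
    if region is None:
        return image
    h, w = image.shape
    if not (0 <= region.lx and region.rx < w and 0 <= region.ty and region.by < h):
        raise IndexError(f"region {region} outside image bounds {w}x{h}")
    return image[region.ty : region.by + 1, region.lx : region.rx + 1]


def build_histogram(image: np.ndarray, region: Box | None = None) -> Histogram:
    """Tally the intensity histogram of ``region`` (whole image if None)."""
    image = _check_grayscale(image)
    sub = _region_view(image, region)
    counts = np.bincount(sub.ravel(), minlength=256).astype(np.int64)
    return Histogram(counts=counts, total=int(sub.size))


def compute_thresholds(
    hist: Histogram, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> ThresholdSet:
    """Derive the five quantization levels from a histogram.

    ``left_value`` is the smallest index at which the left-to-right cumulative
    count first touches or exceeds ``ceil(tail_fraction * total)``;
    ``right_value`` is the symmetric index from the right.  ``t``, ``dt1`` and
    ``dt2`` are integer midpoints (floor division).
    """
    if hist.total <= 0:
        raise ValueError("cannot compute thresholds from an empty histogram")
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie strictly between 0 and 0.5")
    # epsilon guards float error so an exact fraction "touches" its bound
    bound = math.ceil(tail_fraction * hist.total - 1e-9)
    csum = np.cumsum(hist.counts)
    left = int(np.argmax(csum >= bound))
    rsum = np.cumsum(hist.counts[::-1])
    right = 255 - int(np.argmax(rsum >= bound))
    t = (left + right) // 2
    dt1 = (t + left) // 2
    dt2 = (t + right) // 2
    return ThresholdSet(
        left_value=left,
        right_value=right,
        t=t,
        dt1=dt1,
        dt2=dt2,
        tail_fraction=tail_fraction,
    )


def apply_thresholds(values: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Map raw 8-bit values to {0, 127, 255} under ``dt1``/``dt2``."""
    out = np.full(values.shape, GRAY, dtype=np.uint8)
    out[values < thresholds.dt1] = BLACK
    out[values > thresholds.dt2] = WHITE
    return out


def ternarize(
    image: np.ndarray, region: Box | None, thresholds: ThresholdSet
) -> np.ndarray:
    """Quantize ``region`` of ``image`` to a black/gray/white array.

    The output has the dimensions of the region (band-local coordinates).
    """
    image = _check_grayscale(image)
    sub = _region_view(image, region)
    return apply_thresholds(sub, thresholds)


def quantize_region(
    image: np.ndarray,
    region: Box | None = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> tuple[np.ndarray, ThresholdSet]:
    """Histogram -> thresholds -> ternary image for one region, in one call."""
    hist = build_histogram(image, region)
    thresholds = compute_thresholds(hist, tail_fraction)
    return ternarize(image, region, thresholds), thresholds
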