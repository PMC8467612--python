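"""Face-area selection from the ternarized central band of a frame.

The head of a seated driver appears as one large white (bright) connected
component in the middle of the frame once the image is quantized to
black/gray/white.  Selection proceeds in five steps on the central band
(30%..70% of the frame width, full height):

1. ternarize the band with its own dynamic thresholds;
2. replace short vertical black runs with white (glasses frames cut the
   bright head area with thin dark lines);
3. replace short vertical gray runs with white, same bound;
4. replace short horizontal white runs with black (hair speckle above the
   face otherwise drags the top edge of the box upward);
5. grow the white connected component at the band center and return its
   bounding box.

If the band center is not white, the nearest white pixel above and below it
along the center column seeds up to two candidate components; the one whose
bounding box has the smaller width/height ratio (more portrait-shaped, like
a head) is kept.  A component covering almost the entire band is rejected as
a driver-absent artifact: a near-constant frame quantizes to a single flat
region that the run cleanup turns into one huge white block, and emitting a
"face" there would label empty-cabin frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Box, frac_len
from .quantize import (
    BLACK,
    GRAY,
    WHITE,
    DEFAULT_TAIL_FRACTION,
    build_histogram,
    compute_thresholds,
    ternarize,
)

#: Alias used by the public API: a face bounding box is an inclusive Box.
FaceBox = Box

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class FaceAreaParams:
    """Band limits and run-length cleanup bounds, as fractions of frame size."""

    band_left_frac: float = 0.30
    band_right_frac: float = 0.70
    min_black_run_frac_of_height: float = 0.065
    min_gray_run_frac_of_height: float = 0.065
    min_white_run_frac_of_width: float = 0.078
    #: A candidate component covering more than this fraction of the band is
    #: rejected (driver-absent guard).
    max_component_band_frac: float = 0.95
    tail_fraction: float = DEFAULT_TAIL_FRACTION


def band_region(shape: tuple[int, int], params: FaceAreaParams | None = None) -> Box:
    """Central search band: x in [floor(0.30 W), floor(0.70 W)], full height."""
    params = params or FaceAreaParams()
    h, w = shape
    return Box(
        lx=int(params.band_left_frac * w),
        rx=int(params.band_right_frac * w),
        ty=0,
        by=h - 1,
    )


def _run_length_map(mask: np.ndarray, axis: int) -> np.ndarray:
    """Length of the maximal True-run through each pixel (0 where False)."""
    m = mask.astype(np.int32)
    if axis == 0:
        m = m.T
    n, length = m.shape
    fwd = np.empty((n, length), dtype=np.int32)
    run = np.zeros(n, dtype=np.int32)
    for j in range(length):
        run = (run + 1) * m[:, j]
        fwd[:, j] = run
    bwd = np.empty_like(fwd)
    run = np.zeros(n, dtype=np.int32)
    for j in range(length - 1, -1, -1):
        run = (run + 1) * m[:, j]
        bwd[:, j] = run
    total = fwd + bwd - m
    return total if axis == 1 else total.T


def remove_short_vertical_runs(
    img: np.ndarray, value: int, min_len: int
) -> np.ndarray:
    """Replace vertical runs of ``value`` shorter than ``min_len`` with white.

    Runs of exactly ``min_len`` pixels or longer are left untouched (the
    bound is a strict "less than").
    """
    if value not in (BLACK, GRAY):
        raise ValueError("only black or gray runs are removed toward white")
    lengths = _run_length_map(img == value, axis=0)
    out = img.copy()
    out[(lengths > 0) & (lengths < min_len)] = WHITE
    return out


def remove_short_horizontal_white_runs(img: np.ndarray, min_len: int) -> np.ndarray:
    """Replace horizontal white runs shorter than ``min_len`` with black."""
    lengths = _run_length_map(img == WHITE, axis=1)
    out = img.copy()
    out[(lengths > 0) & (lengths < min_len)] = BLACK
    return out


def _component_at(
    labels: np.ndarray, objects: list, label: int
) -> tuple[Box, int]:
    sl_y, sl_x = objects[label - 1]
    count = int(np.count_nonzero(labels[sl_y, sl_x] == label))
    return (
        Box(lx=sl_x.start, rx=sl_x.stop - 1, ty=sl_y.start, by=sl_y.stop - 1),
        count,
    )


def _flood_candidates(
    img: np.ndarray, start: tuple[int, int]
) -> list[tuple[Box, int]]:
    """4-connected white component(s) reachable from ``start`` per the rules."""
    x, y = start
    white = img == WHITE
    labels, _ = ndimage.label(white, structure=_STRUCT4)
    objects = ndimage.find_objects(labels)
    if white[y, x]:
        return [_component_at(labels, objects, labels[y, x])]
    col = white[:, x]
    candidates: list[tuple[Box, int]] = []
    above = np.nonzero(col[:y])[0]
    if above.size:
        candidates.append(_component_at(labels, objects, labels[above[-1], x]))
    below = np.nonzero(col[y + 1 :])[0]
    if below.size:
        candidates.append(_component_at(labels, objects, labels[y + 1 + below[0], x]))
    # The same component may be reached both upward and downward.
    if len(candidates) == 2 and candidates[0] == candidates[1]:
        candidates = candidates[:1]
    return candidates


def flood_select_face(img: np.ndarray, start: tuple[int, int]) -> FaceBox | None:
    """Bounding box of the white component seeded at ``start``.

    If ``start`` is not white, the nearest white pixel above and below along
    the start column each seed a candidate; with two distinct candidates the
    one with the smaller width/height ratio wins (ties keep the upward one).
    Returns None when no white pixel is reachable.
    """
    candidates = _flood_candidates(img, start)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0][0]
    return min(candidates, key=lambda c: c[0].aspect_ratio)[0]


def select_face_area(
    image: np.ndarray, params: FaceAreaParams | None = None
) -> FaceBox | None:
    """Run the five-step face selection; box is in whole-frame coordinates."""
    steps = face_area_steps(image, params)
    return steps["face_box"]


def face_area_steps(
    image: np.ndarray, params: FaceAreaParams | None = None
) -> dict:
    """As :func:`select_face_area` but returning every intermediate image.

    Keys: ``band``, ``step1`` .. ``step4`` (ternary arrays in band
    coordinates), ``thresholds``, ``face_box`` (frame coordinates or None).
    Used by the debug dump and by tests that probe individual steps.
    """
    params = params or FaceAreaParams()
    h, w = image.shape[:2]
    band = band_region((h, w), params)
    hist = build_histogram(image, band)
    thresholds = compute_thresholds(hist, params.tail_fraction)
    step1 = ternarize(image, band, thresholds)

    min_v_black = frac_len(params.min_black_run_frac_of_height, h)
    min_v_gray = frac_len(params.min_gray_run_frac_of_height, h)
    min_h_white = frac_len(params.min_white_run_frac_of_width, w)
    step2 = remove_short_vertical_runs(step1, BLACK, min_v_black)
    step3 = remove_short_vertical_runs(step2, GRAY, min_v_gray)
    step4 = remove_short_horizontal_white_runs(step3, min_h_white)

    start = ((band.width - 1) // 2, (band.height - 1) // 2)
    candidates = _flood_candidates(step4, start)
    face_box: FaceBox | None = None
    if candidates:
        box, count = min(candidates, key=lambda c: c[0].aspect_ratio)
        if count <= params.max_component_band_frac * band.area:
            face_box = box.shifted(band.lx, band.ty)
    return {
        "band": band,
        "thresholds": thresholds,
        "step1": step1,
        "step2": step2,
        "step3": step3,
        "step4": step4,
        "face_box": face_box,
    }
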