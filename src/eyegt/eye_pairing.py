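"""Eye-search regions, window sliding, duels and final pair selection.

The eye search runs inside one of two regions:

* **tracking box** — when the previous frame yielded a pair, a box of
  26% W x 23% H centered on the midpoint of the previous eye locations;
* **face-area box** — otherwise, a larger box anchored at the face box's
  top-left corner, spanning 35% of the frame width and 37% of its height.

The region is traversed by a fixed-size window (5.8% W x 8.7% H) with
strides of 1.1% W / 1.2% H.  Windows that pass the patch filters then fight
pairwise "duels": whenever two surviving candidates overlap, the one with
the lower combined score is discarded, until the survivors are mutually
non-overlapping.  Geometrically valid pairs must sit at a similar height
(|dy| <= 8.7% H) and at a plausible interocular distance (1.5..3 window
widths); the pair with the highest score-sum wins, and the member with the
greater x coordinate is the person's left eye (the camera faces the
driver).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .geometry import Box
from .patch_filters import EyePatch


@dataclass(frozen=True)
class SearchParams:
    """All search-geometry parameters, as fractions of the frame dimensions
    (window-width multiples for the interocular bounds)."""

    track_bbw_frac: float = 0.26
    track_bbh_frac: float = 0.23
    facearea_w_frac: float = 0.35
    facearea_h_frac: float = 0.37
    win_w_frac: float = 0.058
    win_h_frac: float = 0.087
    stride_x_frac: float = 0.011
    stride_y_frac: float = 0.012
    maxY_frac: float = 0.087
    minX_mult: float = 1.5
    maxX_mult: float = 3.0
    #: Average the previous pair's y as printed (left eye's top with right
    #: eye's bottom); set True for the symmetric top+bottom-of-both variant.
    symmetric_avg_y: bool = False

    def window_size(self, frame_shape: tuple[int, int]) -> tuple[int, int]:
        h, w = frame_shape
        return max(1, int(self.win_w_frac * w)), max(1, int(self.win_h_frac * h))

    def strides(self, frame_shape: tuple[int, int]) -> tuple[int, int]:
        h, w = frame_shape
        return max(1, int(self.stride_x_frac * w)), max(1, int(self.stride_y_frac * h))


@dataclass(frozen=True)
class EyeBox:
    """Output bounding box of one eye: top-left corner plus fixed size."""

    ltx: int
    lty: int
    w: int
    h: int


@dataclass(frozen=True)
class EyePair:
    """Ordered detection result; ``left`` is the person's left eye, i.e. the
    box with the greater x coordinate."""

    left: EyeBox
    right: EyeBox
    pair_score: float

    def __post_init__(self) -> None:
        if self.left.ltx <= self.right.ltx:
            raise ValueError("left eye must have the greater x coordinate")


def search_box_from_previous(
    prev: EyePair, frame_shape: tuple[int, int], params: SearchParams | None = None
) -> Box:
    """Tracking box centered on the previous pair's average eye position."""
    params = params or SearchParams()
    h, w = frame_shape
    bbw = max(1, int(params.track_bbw_frac * w))
    bbh = max(1, int(params.track_bbh_frac * h))
    if params.symmetric_avg_y:
        avg_y = (
            prev.left.lty
            + prev.left.lty
            + prev.left.h
            + prev.right.lty
            + prev.right.lty
            + prev.right.h
        ) // 4
    else:
        avg_y = (prev.left.lty + (prev.right.lty + prev.right.h)) // 2
    avg_x = (prev.right.ltx + (prev.left.ltx + prev.left.w)) // 2
    lx = avg_x - bbw // 2
    ty = avg_y - bbh // 2
    return Box(lx=lx, rx=lx + bbw - 1, ty=ty, by=ty + bbh - 1).clipped(w, h)


def search_box_from_face(
    face: Box, frame_shape: tuple[int, int], params: SearchParams | None = None
) -> Box:
    """Search box anchored at the face box's top-left corner."""
    params = params or SearchParams()
    h, w = frame_shape
    return Box(
        lx=face.lx,
        rx=face.lx + int(params.facearea_w_frac * w),
        ty=face.ty,
        by=face.ty + int(params.facearea_h_frac * h),
    ).clipped(w, h)


def slide_windows(
    search_box: Box,
    frame_shape: tuple[int, int],
    params: SearchParams | None = None,
) -> list[tuple[int, int]]:
    """Row-major top-left origins of every window fully inside the box.

    Windows that would poke past the box edge are dropped; an undersized box
    yields an empty list.
    """
    params = params or SearchParams()
    ww, wh = params.window_size(frame_shape)
    sx, sy = params.strides(frame_shape)
    xs = range(search_box.lx, search_box.rx - ww + 2, sx)
    ys = range(search_box.ty, search_box.by - wh + 2, sy)
    return [(x, y) for y in ys for x in xs]


def _boxes_overlap(a: EyePatch, b: EyePatch) -> bool:
    return abs(a.ltx - b.ltx) < a.w and abs(a.lty - b.lty) < a.h


def resolve_overlaps(candidates: list[EyePatch]) -> list[EyePatch]:
    """Duel overlapping candidates until the survivors are disjoint.

    In each duel the lower-scoring patch is eliminated; the winner keeps
    dueling.  With distinct scores the surviving set does not depend on the
    duel order (the best patch always survives, eliminating everything it
    overlaps, and so on down the ranking).  Score ties break toward the
    smaller ``lty``, then the smaller ``ltx``, so outputs stay deterministic.
    """
    ranked = sorted(candidates, key=lambda p: (-p.score, p.lty, p.ltx))
    kept: list[EyePatch] = []
    for patch in ranked:
        if not any(_boxes_overlap(patch, survivor) for survivor in kept):
            kept.append(patch)
    kept_ids = {id(p) for p in kept}
    return [p for p in candidates if id(p) in kept_ids]


def enumerate_pairs(
    survivors: list[EyePatch],
    frame_shape: tuple[int, int],
    params: SearchParams | None = None,
) -> list[tuple[EyePatch, EyePatch]]:
    """All unordered survivor pairs at a plausible eye geometry.

    Constraints on the top-left corners: |y1 - y2| <= floor(0.087 H) and
    1.5 * window_width <= |x1 - x2| <= 3 * window_width.
    """
    params = params or SearchParams()
    h, w = frame_shape
    max_y = int(params.maxY_frac * h)
    ww, _ = params.window_size(frame_shape)
    min_x = params.minX_mult * ww
    max_x = params.maxX_mult * ww
    pairs = []
    for a, b in itertools.combinations(survivors, 2):
        if abs(a.lty - b.lty) <= max_y and min_x <= abs(a.ltx - b.ltx) <= max_x:
            pairs.append((a, b))
    return pairs


def select_final_pair(
    pairs: list[tuple[EyePatch, EyePatch]]
) -> EyePair | None:
    """Highest score-sum pair, ordered left/right; None when no pair exists."""
    if not pairs:
        return None
    best = max(pairs, key=lambda pq: pq[0].score + pq[1].score)
    a, b = best
    left, right = (a, b) if a.ltx > b.ltx else (b, a)
    return EyePair(
        left=EyeBox(ltx=left.ltx, lty=left.lty, w=left.w, h=left.h),
        right=EyeBox(ltx=right.ltx, lty=right.lty, w=right.w, h=right.h),
        pair_score=a.score + b.score,
    )
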