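"""Per-patch filters that decide whether a window-sized region is an eye.

Each candidate window is quantized to black/gray/white with its own
thresholds and then passed through three stages:

* **black percentages rule** — the fractions of black pixels in three
  sub-regions of the patch must each fall inside a configured range.  An
  eye patch has a mostly-dark core (iris/pupil) in its center, a moderate
  overall dark fraction, and little darkness in its top band (forehead
  skin).  This cheap test prunes the overwhelming majority of windows.
* **ratio-map score** — a confidence score (never a rejection) measuring
  how elongated-horizontal the dark area is.  For every black pixel the
  maximal horizontal and vertical black-run lengths through it are
  computed; pixels whose horizontal/vertical ratio strictly exceeds 1.3
  become white in the ratio map.  The score is the white percentage of the
  map's central third.  The dark eye band is roughly a flat-lying
  rectangle, so true eyes score high.
* **pupil reflection check** — mandatory: the central third must contain a
  small, isolated white spot (the corneal glint of the infrared
  illuminator), with 4..24 pixels and at least 3 black pixels outward from
  the midpoint of each side of its bounding box.  Bright specks on skin
  fail the margin test because their surroundings are white.

The patch score is ``b1 + b2 + b3 + r`` (each term a percentage, so the
score ranges over 0..400).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Box
from .quantize import BLACK, WHITE

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Fixed run-length ratio above which a pixel counts as "eye shaped".
DEFAULT_RATIO_THRESHOLD = 1.3

#: Pupil-glint pixel-count bounds.  These are absolute pixel counts, not
#: fractions of the frame: the glint size is a property of the illuminator
#: and sensor, not of the image resolution.
DEFAULT_PUPIL_MIN_PX = 4
DEFAULT_PUPIL_MAX_PX = 24
DEFAULT_PUPIL_MARGIN = 3


def middle_region(w: int, h: int, fraction: float = 1.0 / 3.0) -> Box:
    """Centered sub-box of a ``w`` x ``h`` patch, scaled by ``fraction``.

    Width and height are floored; centering offsets are floored too, so the
    box leans toward the top-left on odd remainders.
    """
    if w < 3 or h < 3:
        raise ValueError("patch must be at least 3x3")
    mw = max(1, int(w * fraction))
    mh = max(1, int(h * fraction))
    x0 = (w - mw) // 2
    y0 = (h - mh) // 2
    return Box(lx=x0, rx=x0 + mw - 1, ty=y0, by=y0 + mh - 1)


@dataclass(frozen=True)
class RegionSpec:
    """One black-rule region: the patch's centered middle third, or a
    rectangle given as fractions of the patch width/height."""

    kind: str = "rect"  # "rect" | "middle"
    x0: float = 0.0
    y0: float = 0.0
    x1: float = 1.0
    y1: float = 1.0

    def resolve(self, w: int, h: int) -> Box:
        if self.kind == "middle":
            return middle_region(w, h)
        lx = int(self.x0 * w)
        ty = int(self.y0 * h)
        rx = min(w - 1, int(self.x1 * w) - 1) if self.x1 < 1.0 else w - 1
        by = min(h - 1, int(self.y1 * h) - 1) if self.y1 < 1.0 else h - 1
        if rx < lx or by < ty:
            raise ValueError(f"black-rule region resolves to zero area: {self}")
        return Box(lx=lx, rx=rx, ty=ty, by=by)


@dataclass(frozen=True)
class BlackRuleConfig:
    """Three regions with inclusive [min%, max%] black-percentage ranges.

    Defaults: R1 the eye core (centered middle third, mostly dark), R2 the
    full patch (moderately dark), R3 the top band (full width x top 25%,
    mostly bright forehead skin).
    """

    regions: tuple[RegionSpec, RegionSpec, RegionSpec] = (
        RegionSpec(kind="middle"),
        RegionSpec(kind="rect", x0=0.0, y0=0.0, x1=1.0, y1=1.0),
        RegionSpec(kind="rect", x0=0.0, y0=0.0, x1=1.0, y1=0.25),
    )
    ranges: tuple[tuple[float, float], ...] = ((50.0, 100.0), (15.0, 75.0), (0.0, 45.0))

    def __post_init__(self) -> None:
        if len(self.regions) != 3 or len(self.ranges) != 3:
            raise ValueError("the black rule takes exactly three regions")
        for lo, hi in self.ranges:
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError("black-rule range must satisfy 0 <= min <= max <= 100")


@dataclass(frozen=True)
class PupilSpot:
    """A white glint candidate: bounding box in patch coordinates + size."""

    box: Box
    pixel_count: int


@dataclass
class EyePatch:
    """A window-sized candidate region with its filter state.

    Filter fields start unset; :func:`score_patch` (and the ``score``
    property) refuse to run until all four terms have been computed.
    """

    ltx: int
    lty: int
    w: int
    h: int
    ternary: np.ndarray
    b1: float | None = None
    b2: float | None = None
    b3: float | None = None
    r: float | None = None
    has_pupil: bool | None = None
    pupil_spot: PupilSpot | None = field(default=None, repr=False)

    @property
    def score(self) -> float:
        if None in (self.b1, self.b2, self.b3, self.r):
            raise RuntimeError(
                "patch score requested before the black rule and ratio map ran"
            )
        return self.b1 + self.b2 + self.b3 + self.r


def black_percentages(
    patch: EyePatch, cfg: BlackRuleConfig | None = None
) -> tuple[float, float, float, bool]:
    """Black-pixel percentages of the three configured regions + pass flag.

    Side effect: stores ``b1``..``b3`` on the patch.
    """
    cfg = cfg or BlackRuleConfig()
    black = patch.ternary == BLACK
    values: list[float] = []
    ok = True
    for spec, (lo, hi) in zip(cfg.regions, cfg.ranges):
        box = spec.resolve(patch.w, patch.h)
        region = black[box.ty : box.by + 1, box.lx : box.rx + 1]
        pct = 100.0 * float(np.count_nonzero(region)) / box.area
        values.append(pct)
        ok = ok and lo <= pct <= hi
    patch.b1, patch.b2, patch.b3 = values
    return values[0], values[1], values[2], ok


def _run_length_map(mask: np.ndarray, axis: int) -> np.ndarray:
    # Maximal-run length through each True pixel; 0 elsewhere.
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


def ratio_map(
    ternary: np.ndarray, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> np.ndarray:
    """Binary map: white where a black pixel's horizontal run is more than
    ``ratio_threshold`` times its vertical run; black everywhere else.

    White and gray input pixels are equivalent here (the first step of the
    construction merges them), so the map depends only on the black mask.
    """
    black = ternary == BLACK
    h_runs = _run_length_map(black, axis=1)
    v_runs = _run_length_map(black, axis=0)
    out = np.full(ternary.shape, BLACK, dtype=np.uint8)
    out[black & (h_runs > ratio_threshold * v_runs)] = WHITE
    return out


def ratio_map_score(
    patch: EyePatch, ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
) -> float:
    """White percentage of the ratio map's central third; stored as ``r``."""
    rmap = ratio_map(patch.ternary, ratio_threshold)
    mid = middle_region(patch.w, patch.h)
    sub = rmap[mid.ty : mid.by + 1, mid.lx : mid.rx + 1]
    patch.r = 100.0 * float(np.count_nonzero(sub == WHITE)) / mid.area
    return patch.r


def _components_raster_order(mask: np.ndarray) -> list[tuple[Box, int]]:
    labels, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 0:
        return []
    objects = ndimage.find_objects(labels)
    flat = labels.ravel()
    first_index = {}
    for idx in np.nonzero(flat)[0]:
        lab = flat[idx]
        if lab not in first_index:
            first_index[lab] = idx
            if len(first_index) == n:
                break
    out = []
    for lab in sorted(first_index, key=first_index.get):
        sl_y, sl_x = objects[lab - 1]
        count = int(np.count_nonzero(labels[sl_y, sl_x] == lab))
        box = Box(lx=sl_x.start, rx=sl_x.stop - 1, ty=sl_y.start, by=sl_y.stop - 1)
        out.append((box, count))
    return out


def pupil_reflection_check(
    patch: EyePatch,
    min_px: int = DEFAULT_PUPIL_MIN_PX,
    max_px: int = DEFAULT_PUPIL_MAX_PX,
    margin: int = DEFAULT_PUPIL_MARGIN,
) -> tuple[bool, PupilSpot | None]:
    """Search the patch's central third for a valid glint.

    A 4-connected white spot passes when its pixel count lies in
    [``min_px``, ``max_px``] and the ``margin`` pixels extending outward
    from the midpoint of each bounding-box edge are all black.  Pixels
    outside the patch count as non-black, so a spot hugging the patch
    border fails in that direction.  The first passing spot in raster order
    wins.  Side effect: sets ``has_pupil`` / ``pupil_spot``.
    """
    mid = middle_region(patch.w, patch.h)
    sub = patch.ternary[mid.ty : mid.by + 1, mid.lx : mid.rx + 1] == WHITE
    tern = patch.ternary
    for box, count in _components_raster_order(sub):
        if not min_px <= count <= max_px:
            continue
        spot = Box(
            lx=box.lx + mid.lx,
            rx=box.rx + mid.lx,
            ty=box.ty + mid.ty,
            by=box.by + mid.ty,
        )
        cx = (spot.lx + spot.rx) // 2
        cy = (spot.ty + spot.by) // 2
        probes = (
            [(cx, spot.ty - 1 - k) for k in range(margin)]
            + [(cx, spot.by + 1 + k) for k in range(margin)]
            + [(spot.lx - 1 - k, cy) for k in range(margin)]
            + [(spot.rx + 1 + k, cy) for k in range(margin)]
        )
        surrounded = all(
            0 <= px < patch.w and 0 <= py < patch.h and tern[py, px] == BLACK
            for px, py in probes
        )
        if surrounded:
            patch.has_pupil = True
            patch.pupil_spot = PupilSpot(box=spot, pixel_count=count)
            return True, patch.pupil_spot
    patch.has_pupil = False
    patch.pupil_spot = None
    return False, None


def score_patch(patch: EyePatch) -> float:
    """Combined validation score ``b1 + b2 + b3 + r`` (0..400)."""
    return patch.score
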