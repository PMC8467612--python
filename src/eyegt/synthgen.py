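"""Seeded synthetic infrared driver-frame generator with exact ground truth.

The detector assumes a very specific image structure from an in-cabin
infrared camera: a dark background (seat, ceiling), a strongly illuminated
face, dark eye regions each holding a tiny bright corneal glint, and
occasional confounders (dark glasses-frame bars, hair speckle at the top of
the face, a bright surgical-mask band).  This module renders frames with
exactly that intensity layering::

    background (10..40)  <  eye region (30..70)  <  face skin (150..220)
                                                 <  glint (250..255)

so that frame-level quantization maps background to black and the face to
white, and patch-level quantization maps the eye region to black with the
glint as an isolated white spot.  No attempt at photorealism is made — the
point is to exercise every detection rule with known geometry.

Every frame is a pure function of its :class:`SceneSpec` (including its
seed), so tests and the acceptance checks are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import Box

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EyeSpec:
    """One eye: a dark ellipse with an optional centered glint square."""

    center: tuple[int, int]
    axes: tuple[int, int] = (28, 16)
    intensity: tuple[int, int] = (30, 70)
    glint_shape: tuple[int, int] = (3, 3)
    glint_intensity: tuple[int, int] = (250, 255)
    is_open: bool = True

    @property
    def glint_pixels(self) -> int:
        return self.glint_shape[0] * self.glint_shape[1]


@dataclass(frozen=True)
class GlassesSpec:
    """Dark horizontal bar across the face, optionally with a small bright
    reflection on the bar — the known failure mode of the pupil check."""

    y: int
    thickness: int = 8
    intensity: tuple[int, int] = (15, 55)
    reflection: tuple[int, int] | None = None  # center of a 2x2 bright blob
    reflection_intensity: tuple[int, int] = (250, 255)


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-frame labels for evaluating the detector."""

    face_box: Box | None
    left_pupil: tuple[int, int] | None
    right_pupil: tuple[int, int] | None
    eyes_open: bool
    driver_present: bool
    glasses_reflection: bool = False


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic frame.

    Defaults place a portrait-shaped face in the central band of a
    1280x800 frame with eyes 160 px apart — i.e. inside every geometric
    constraint the detector imposes at that resolution.
    """

    width: int = 1280
    height: int = 800
    background: tuple[int, int] = (10, 40)
    face_center: tuple[int, int] = (640, 420)
    face_axes: tuple[int, int] = (210, 280)
    face_intensity: tuple[int, int] = (150, 220)
    left_eye: EyeSpec = field(default_factory=lambda: EyeSpec(center=(720, 340)))
    right_eye: EyeSpec = field(default_factory=lambda: EyeSpec(center=(560, 340)))
    glasses: GlassesSpec | None = None
    hair_noise_rows: int = 0
    hair_noise_density: float = 0.45
    mask_band: bool = False
    noise_amplitude: int = 2
    driver_present: bool = True
    seed: int = 0

    # -- geometry helpers -------------------------------------------------

    def _eyes(self) -> tuple[EyeSpec, EyeSpec]:
        return self.right_eye, self.left_eye

    def validate(self) -> None:
        fx, fy = self.face_center
        fa, fb = self.face_axes
        for eye in self._eyes():
            ex, ey = eye.center
            ax, ay = eye.axes
            for px, py in ((ex - ax, ey), (ex + ax, ey), (ex, ey - ay), (ex, ey + ay)):
                if ((px - fx) / fa) ** 2 + ((py - fy) / fb) ** 2 > 1.0:
                    raise ValueError(f"eye at {eye.center} extends outside the face")
            gw, gh = eye.glint_shape
            if gw > 2 * ax - 2 or gh > 2 * ay - 2:
                raise ValueError("glint does not fit inside the eye region")
            if eye.glint_pixels < 1:
                raise ValueError("glint must have at least one pixel")
        lo, hi = self.background
        if not 0 <= lo <= hi <= 255:
            raise ValueError("invalid background intensity range")

    def shifted(self, dx: int, dy: int) -> "SceneSpec":
        """Translate face, eyes and glasses rigidly by (dx, dy)."""

        def move(eye: EyeSpec) -> EyeSpec:
            return dataclasses.replace(
                eye, center=(eye.center[0] + dx, eye.center[1] + dy)
            )

        glasses = self.glasses
        if glasses is not None:
            refl = glasses.reflection
            glasses = dataclasses.replace(
                glasses,
                y=glasses.y + dy,
                reflection=None if refl is None else (refl[0] + dx, refl[1] + dy),
            )
        return dataclasses.replace(
            self,
            face_center=(self.face_center[0] + dx, self.face_center[1] + dy),
            left_eye=move(self.left_eye),
            right_eye=move(self.right_eye),
            glasses=glasses,
        )


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[int, int], axes: tuple[int, int]
) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    ax, ay = axes
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _fill(
    img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
    intensity: tuple[int, int],
) -> None:
    img[mask] = rng.integers(intensity[0], intensity[1] + 1, int(mask.sum()))


def render_frame(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame; deterministic given ``spec`` (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = rng.integers(
        spec.background[0], spec.background[1] + 1, size=(h, w), dtype=np.int16
    )

    face_box: Box | None = None
    if spec.driver_present:
        fmask = _ellipse_mask((h, w), spec.face_center, spec.face_axes)
        _fill(img, fmask, rng, spec.face_intensity)
        ys, xs = np.nonzero(fmask)
        face_box = Box(lx=int(xs.min()), rx=int(xs.max()),
                       ty=int(ys.min()), by=int(ys.max()))

        if spec.hair_noise_rows > 0:
            yy = np.arange(h)[:, None]
            top = spec.face_center[1] - spec.face_axes[1]
            band = fmask & (yy < top + spec.hair_noise_rows)
            speckle = band & (rng.random((h, w)) < spec.hair_noise_density)
            _fill(img, speckle, rng, (15, 60))

        if spec.mask_band:
            yy = np.arange(h)[:, None]
            cy = spec.face_center[1]
            band = fmask & (yy > cy + int(0.25 * spec.face_axes[1]))
            _fill(img, band, rng, (200, 240))

        for eye in spec._eyes():
            emask = _ellipse_mask((h, w), eye.center, eye.axes)
            _fill(img, emask, rng, eye.intensity)
            if eye.is_open:
                gw, gh = eye.glint_shape
                gx = eye.center[0] - gw // 2
                gy = eye.center[1] - gh // 2
                img[gy : gy + gh, gx : gx + gw] = rng.integers(
                    eye.glint_intensity[0], eye.glint_intensity[1] + 1, (gh, gw)
                )

        if spec.glasses is not None:
            g = spec.glasses
            rows = slice(g.y, g.y + g.thickness)
            bar = np.zeros((h, w), dtype=bool)
            bar[rows] = fmask[rows]
            _fill(img, bar, rng, g.intensity)
            if g.reflection is not None:
                rx, ry = g.reflection
                img[ry : ry + 2, rx : rx + 2] = rng.integers(
                    g.reflection_intensity[0], g.reflection_intensity[1] + 1, (2, 2)
                )

    if spec.noise_amplitude > 0:
        a = spec.noise_amplitude
        img = img + rng.integers(-a, a + 1, size=(h, w), dtype=np.int16)

    frame = np.clip(img, 0, 255).astype(np.uint8)
    present = spec.driver_present
    truth = GroundTruth(
        face_box=face_box,
        left_pupil=spec.left_eye.center if present else None,
        right_pupil=spec.right_eye.center if present else None,
        eyes_open=present and spec.left_eye.is_open and spec.right_eye.is_open,
        driver_present=present,
        glasses_reflection=bool(
            present and spec.glasses is not None and spec.glasses.reflection
        ),
    )
    return frame, truth


def render_sequence(
    spec: SceneSpec,
    n_frames: int,
    drift: tuple[int, int] = (0, 0),
    seed: int | None = None,
    open_schedule: list[bool] | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Frames with rigid per-frame drift of the whole face geometry.

    Frame ``i`` is the base spec shifted by ``i * drift`` and seeded with
    ``base_seed + i``, so geometry follows the drift exactly while the noise
    stream differs per frame.  ``open_schedule`` optionally toggles both
    eyes open/closed per frame.
    """
    base_seed = spec.seed if seed is None else seed
    out = []
    for i in range(n_frames):
        s = spec.shifted(drift[0] * i, drift[1] * i)
        s = dataclasses.replace(s, seed=(base_seed + i) % _SEED_MOD)
        if open_schedule is not None:
            is_open = bool(open_schedule[i])
            s = dataclasses.replace(
                s,
                left_eye=dataclasses.replace(s.left_eye, is_open=is_open),
                right_eye=dataclasses.replace(s.right_eye, is_open=is_open),
            )
        out.append(render_frame(s))
    return out


def scenario(name: str, seed: int = 0) -> SceneSpec:
    """Canned scene specs: ``open``, ``closed``, ``empty``, ``glasses``,
    ``glasses_reflection``, ``hair``."""
    base = SceneSpec(seed=seed % _SEED_MOD)
    if name == "open":
        return base
    if name == "closed":
        return dataclasses.replace(
            base,
            left_eye=dataclasses.replace(base.left_eye, is_open=False),
            right_eye=dataclasses.replace(base.right_eye, is_open=False),
        )
    if name == "empty":
        return dataclasses.replace(base, driver_present=False)
    if name == "glasses":
        return dataclasses.replace(base, glasses=GlassesSpec(y=368))
    if name == "glasses_reflection":
        return dataclasses.replace(
            base, glasses=GlassesSpec(y=368, reflection=(660, 371))
        )
    if name == "hair":
        return dataclasses.replace(base, hair_noise_rows=60)
    raise ValueError(f"unknown scenario {name!r}")
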