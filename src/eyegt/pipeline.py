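"""Frame-sequence orchestration, label output and configuration.

The per-frame flow is: pick the search region (tracking box from the
previous frame's pair when available, otherwise detect the face area and
anchor the larger search box there), slide the fixed-size window across it,
quantize each window with its own thresholds, apply the black-percentages
rule, the ratio-map score and the mandatory pupil-reflection check, duel
overlapping candidates, enumerate geometrically valid pairs and keep the
best-scoring one.  A sequence keeps the last detected pair as tracking
state and resets it after any miss.

Labels are written as CSV (fixed header) or JSON, with a summary of
processed / detected / no_face / no_pair / error counts.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import face_area as fa
from . import eye_pairing as ep
from . import patch_filters as pf
from .geometry import Box
from .quantize import DEFAULT_TAIL_FRACTION, _check_grayscale, quantize_region

log = logging.getLogger("eyegt")

LABEL_HEADER = ["frame_id", "left_ltx", "left_lty", "right_ltx", "right_lty", "w", "h"]

STATUS_DETECTED = "detected"
STATUS_NO_FACE = "no_face"
STATUS_NO_PAIR = "no_pair"
STATUS_ERROR = "error"


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with the published defaults."""

    tail_fraction: float = DEFAULT_TAIL_FRACTION
    face: fa.FaceAreaParams = field(default_factory=fa.FaceAreaParams)
    search: ep.SearchParams = field(default_factory=ep.SearchParams)
    black_rule: pf.BlackRuleConfig = field(default_factory=pf.BlackRuleConfig)
    ratio_threshold: float = pf.DEFAULT_RATIO_THRESHOLD
    pupil_min_px: int = pf.DEFAULT_PUPIL_MIN_PX
    pupil_max_px: int = pf.DEFAULT_PUPIL_MAX_PX
    pupil_margin: int = pf.DEFAULT_PUPIL_MARGIN

    # -- YAML round trip --------------------------------------------------

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "face" in kwargs:
            kwargs["face"] = fa.FaceAreaParams(**kwargs["face"])
        if "search" in kwargs:
            kwargs["search"] = ep.SearchParams(**kwargs["search"])
        if "black_rule" in kwargs:
            br = dict(kwargs["black_rule"])
            if "regions" in br:
                br["regions"] = tuple(pf.RegionSpec(**r) for r in br["regions"])
            if "ranges" in br:
                br["ranges"] = tuple(tuple(r) for r in br["ranges"])
            kwargs["black_rule"] = pf.BlackRuleConfig(**br)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


@dataclass
class FrameResult:
    """Per-frame detection outcome plus instrumentation.

    ``status`` is ``detected`` iff ``pair`` is present.  ``search_box`` /
    ``search_source`` record which region was scanned (``tracking`` or
    ``face_area``); the window counters feed pruning statistics.
    """

    frame_id: str
    status: str
    pair: ep.EyePair | None = None
    face: Box | None = None
    search_box: Box | None = None
    search_source: str | None = None
    n_windows: int = 0
    n_black_pass: int = 0
    n_candidates: int = 0
    error: str | None = None


def load_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit PNG/PGM frame; reject multi-channel data."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    return _check_grayscale(arr)


def extract_patches(
    image: np.ndarray,
    origins: Iterable[tuple[int, int]],
    window: tuple[int, int],
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> list[pf.EyePatch]:
    """Cut windows at ``origins`` and quantize each with its own thresholds."""
    ww, wh = window
    patches = []
    for x, y in origins:
        region = Box(lx=x, rx=x + ww - 1, ty=y, by=y + wh - 1)
        ternary, _ = quantize_region(image, region, tail_fraction)
        patches.append(pf.EyePatch(ltx=x, lty=y, w=ww, h=wh, ternary=ternary))
    return patches


def process_frame(
    image: np.ndarray,
    previous: ep.EyePair | None = None,
    config: PipelineConfig | None = None,
    frame_id: str = "frame",
) -> FrameResult:
    """Detect the eye pair on one frame.

    ``previous`` is the pair detected on the preceding frame (enables the
    tracking search box); without it the face area is located first and a
    missing face yields status ``no_face``.
    """
    config = config or PipelineConfig()
    try:
        image = _check_grayscale(image)
    except ValueError as exc:
        raise ValueError(f"frame {frame_id!r}: {exc}") from exc
    shape = image.shape

    face: Box | None = None
    if previous is not None:
        search_box = ep.search_box_from_previous(previous, shape, config.search)
        source = "tracking"
    else:
        face = fa.select_face_area(image, config.face)
        if face is None:
            return FrameResult(frame_id=frame_id, status=STATUS_NO_FACE)
        search_box = ep.search_box_from_face(face, shape, config.search)
        source = "face_area"

    origins = ep.slide_windows(search_box, shape, config.search)
    window = config.search.window_size(shape)

    candidates: list[pf.EyePatch] = []
    n_black_pass = 0
    for patch in extract_patches(image, origins, window, config.tail_fraction):
        _, _, _, ok = pf.black_percentages(patch, config.black_rule)
        if not ok:
            continue
        n_black_pass += 1
        pf.ratio_map_score(patch, config.ratio_threshold)
        has_pupil, _ = pf.pupil_reflection_check(
            patch, config.pupil_min_px, config.pupil_max_px, config.pupil_margin
        )
        if has_pupil:
            candidates.append(patch)

    survivors = ep.resolve_overlaps(candidates)
    pairs = ep.enumerate_pairs(survivors, shape, config.search)
    pair = ep.select_final_pair(pairs)

    return FrameResult(
        frame_id=frame_id,
        status=STATUS_DETECTED if pair is not None else STATUS_NO_PAIR,
        pair=pair,
        face=face,
        search_box=search_box,
        search_source=source,
        n_windows=len(origins),
        n_black_pass=n_black_pass,
        n_candidates=len(candidates),
    )


def process_sequence(
    frames: Sequence[np.ndarray] | Iterable[np.ndarray],
    config: PipelineConfig | None = None,
    frame_ids: Sequence[str] | None = None,
) -> list[FrameResult]:
    """Process frames in order with single-miss tracking reset.

    A detected frame seeds the next frame's tracking box; any miss (or
    per-frame error, which is logged and recorded rather than aborting the
    run) falls back to face-area search on the following frame.
    """
    config = config or PipelineConfig()
    results: list[FrameResult] = []
    previous: ep.EyePair | None = None
    for i, frame in enumerate(frames):
        fid = frame_ids[i] if frame_ids is not None else f"{i:06d}"
        try:
            result = process_frame(frame, previous, config, frame_id=fid)
        except Exception as exc:  # noqa: BLE001 - recorded per frame
            log.warning("frame %s failed: %s", fid, exc)
            result = FrameResult(frame_id=fid, status=STATUS_ERROR, error=str(exc))
        results.append(result)
        previous = result.pair if result.status == STATUS_DETECTED else None
    return results


def summarize(results: Sequence[FrameResult]) -> dict[str, int]:
    counts = {"processed": len(results), "detected": 0, "no_face": 0,
              "no_pair": 0, "errors": 0}
    keymap = {STATUS_DETECTED: "detected", STATUS_NO_FACE: "no_face",
              STATUS_NO_PAIR: "no_pair", STATUS_ERROR: "errors"}
    for r in results:
        counts[keymap[r.status]] += 1
    return counts


def _records(results: Sequence[FrameResult]) -> list[dict]:
    recs = []
    for r in results:
        if r.pair is None:
            continue
        recs.append({
            "frame_id": r.frame_id,
            "left_ltx": r.pair.left.ltx,
            "left_lty": r.pair.left.lty,
            "right_ltx": r.pair.right.ltx,
            "right_lty": r.pair.right.lty,
            "w": r.pair.left.w,
            "h": r.pair.left.h,
        })
    return recs


def write_labels(
    results: Sequence[FrameResult], path: str | Path, format: str = "csv"
) -> None:
    """Write one record per detected frame plus a run summary.

    CSV keeps the fixed header and appends the summary as ``#`` comment
    lines; JSON nests ``records`` and ``summary`` objects.  Output is
    byte-identical for identical inputs.
    """
    path = Path(path)
    records = _records(results)
    summary = summarize(results)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=LABEL_HEADER, lineterminator="\n")
        writer.writeheader()
        writer.writerows(records)
        for key, value in summary.items():
            buf.write(f"# {key}={value}\n")
        path.write_text(buf.getvalue())
    elif format == "json":
        path.write_text(
            json.dumps({"records": records, "summary": summary}, indent=2) + "\n"
        )
    else:
        raise ValueError(f"unknown label format {format!r}")


def read_labels(path: str | Path) -> tuple[list[dict], dict[str, int]]:
    """Read a label file written by :func:`write_labels` (either format)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        data = json.loads(text)
        return data["records"], data["summary"]
    summary: dict[str, int] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            summary[key] = int(value)
        elif line:
            rows.append(line)
    records = []
    for rec in csv.DictReader(rows):
        records.append(
            {k: (rec[k] if k == "frame_id" else int(rec[k])) for k in LABEL_HEADER}
        )
    return records, summary


def draw_result(image: np.ndarray, result: FrameResult) -> np.ndarray:
    """Overlay for debugging: face box (gray), search box (mid), eyes (white)."""
    out = np.asarray(image).copy()

    def outline(box: Box | None, value: int) -> None:
        if box is None:
            return
        b = box.clipped(out.shape[1], out.shape[0])
        out[b.ty, b.lx : b.rx + 1] = value
        out[b.by, b.lx : b.rx + 1] = value
        out[b.ty : b.by + 1, b.lx] = value
        out[b.ty : b.by + 1, b.rx] = value

    outline(result.face, 127)
    outline(result.search_box, 180)
    if result.pair is not None:
        for eye in (result.pair.left, result.pair.right):
            outline(Box(eye.ltx, eye.ltx + eye.w - 1, eye.lty, eye.lty + eye.h - 1), 255)
    return out
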