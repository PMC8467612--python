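"""Inclusive axis-aligned pixel boxes.

The whole pipeline works in image coordinates with the origin at the top-left
corner, x growing rightward and y growing downward.  Boxes store all four
edges inclusively: a box with ``lx == rx`` and ``ty == by`` is a single pixel.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Box:
    """Inclusive bounding box (left x, right x, top y, bottom y)."""

    lx: int
    rx: int
    ty: int
    by: int

    def __post_init__(self) -> None:
        if self.lx > self.rx or self.ty > self.by:
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> int:
        return self.rx - self.lx + 1

    @property
    def height(self) -> int:
        return self.by - self.ty + 1

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def aspect_ratio(self) -> float:
        """Width divided by height."""
        return self.width / self.height

    def contains_point(self, x: int, y: int) -> bool:
        return self.lx <= x <= self.rx and self.ty <= y <= self.by

    def shifted(self, dx: int, dy: int) -> "Box":
        return Box(self.lx + dx, self.rx + dx, self.ty + dy, self.by + dy)

    def clipped(self, width: int, height: int) -> "Box":
        """Clip to a ``width`` x ``height`` frame (may shrink the box)."""
        return Box(
            max(0, self.lx),
            min(width - 1, self.rx),
            max(0, self.ty),
            min(height - 1, self.by),
        )

    @classmethod
    def full(cls, width: int, height: int) -> "Box":
        return cls(0, width - 1, 0, height - 1)


def frac_len(fraction: float, dimension: int) -> int:
    """Pixel length of a fraction of an image dimension: max(1, floor)."""
    return max(1, int(fraction * dimension))
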