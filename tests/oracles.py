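"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as naively as possible (python loops, BFS) and
must stay independent of the package's own code paths.
"""

from __future__ import annotations

import math
from collections import deque


def threshold_scan_oracle(counts, total, tail_fraction):
    """Literal cumulative scan: left/right trimmed indices and midpoints."""
    # same epsilon as the contract: an exactly-reached fraction "touches"
    bound = math.ceil(tail_fraction * total - 1e-9)
    acc = 0
    left = 255
    for i in range(256):
        acc += counts[i]
        if acc >= bound:
            left = i
            break
    acc = 0
    right = 0
    for i in range(255, -1, -1):
        acc += counts[i]
        if acc >= bound:
            right = i
            break
    t = (left + right) // 2
    return left, right, t, (t + left) // 2, (t + right) // 2


def tally_histogram_oracle(image, box):
    """Per-pixel tally of an inclusive region."""
    counts = [0] * 256
    for y in range(box.ty, box.by + 1):
        for x in range(box.lx, box.rx + 1):
            counts[int(image[y, x])] += 1
    return counts


def bfs_components(mask):
    """4-connected True components of a 2D boolean array.

    Returns a list of (pixel set, (lx, rx, ty, by)) in raster order of each
    component's first pixel.
    """
    h = len(mask)
    w = len(mask[0])
    seen = [[False] * w for _ in range(h)]
    components = []
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0][x0] or seen[y0][x0]:
                continue
            pixels = set()
            queue = deque([(x0, y0)])
            seen[y0][x0] = True
            while queue:
                x, y = queue.popleft()
                pixels.add((x, y))
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nx, ny = x + dx, y + dy
                    if 0 <= nx < w and 0 <= ny < h and mask[ny][nx] and not seen[ny][nx]:
                        seen[ny][nx] = True
                        queue.append((nx, ny))
            xs = [p[0] for p in pixels]
            ys = [p[1] for p in pixels]
            components.append((pixels, (min(xs), max(xs), min(ys), max(ys))))
    return components


def component_box_at(mask, x, y):
    """Bounding box of the component containing (x, y), or None."""
    if not mask[y][x]:
        return None
    for pixels, box in bfs_components(mask):
        if (x, y) in pixels:
            return box
    return None


def slide_count_formula(box_w, box_h, win_w, win_h, sx, sy):
    """Closed-form number of fully-contained strided windows."""
    if box_w < win_w or box_h < win_h:
        return 0
    return ((box_w - win_w) // sx + 1) * ((box_h - win_h) // sy + 1)
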