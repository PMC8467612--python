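# eyegt — automatic eye-location ground truth for infrared driver frames

Training eye-detection networks for driver monitoring needs large labeled
datasets, and manual annotation of infrared cabin recordings is slow and
error-prone. `eyegt` implements a deterministic detection pipeline that
generates those labels automatically: given single-channel 8-bit frames from
an in-cabin infrared camera (dark background, strongly illuminated face), it
emits per-frame bounding boxes for the left and right eye — designed to be
very precise at the cost of not firing on every frame, which is the right
trade-off for a ground-truth generator.

Because the original recordings are proprietary, the package ships a seeded
synthetic-frame generator that reproduces the statistical structure the
detector relies on (intensity layering, glints, glasses/hair confounders)
with exact ground truth, so every stage is testable end to end.

## The algorithm

All parameters are fractions of the frame width `W` and height `H`, so any
resolution works; the reference geometry is 1280×800.

1. **Ternary quantization.** For each region of interest, accumulate its
   256-bin histogram from both ends until a tail fraction (default 17%) of
   the pixels is covered, giving a trimmed range `[left, right]`. With
   `t = (left + right) / 2`, the double thresholds `dt1 = (left + t) / 2`
   and `dt2 = (t + right) / 2` map each pixel to black (`x < dt1`), gray
   (`dt1 ≤ x ≤ dt2`) or white (`x > dt2`). Thresholds are recomputed for
   every frame band and every candidate patch.
2. **Face area.** Quantize the central band (30%–70% of `W`), remove
   vertical black and gray runs shorter than 6.5% `H` (glasses bars), remove
   horizontal white runs shorter than 7.8% `W` (hair speckle), then grow the
   white connected component at the band center; its bounding box is the
   face area.
3. **Eye search.** Slide a 5.8% `W` × 8.7% `H` window (strides 1.1% `W`,
   1.2% `H`) over the search region — a 26% `W` × 23% `H` box centered on
   the previous frame's eyes when tracking, otherwise a 35% `W` × 37% `H`
   box anchored at the face area's top-left corner.
4. **Patch filters.** Each window, quantized with its own thresholds, must
   pass the black-percentages rule (dark eye core, moderate overall
   darkness, bright forehead band) and the pupil-reflection check (an
   isolated 4–24 px white glint in the central third, surrounded by ≥ 3
   black pixels on each side). A ratio-map score `r` measures how
   horizontally elongated the dark region is (run-length ratio > 1.3).
5. **Pair selection.** Overlapping candidates duel — the lower combined
   score `b1 + b2 + b3 + r` loses — and surviving patches form pairs when
   `|Δy| ≤ 8.7% H` and `1.5·w ≤ |Δx| ≤ 3·w` (window width `w`). The
   highest-scoring pair wins; the member with the greater x coordinate is
   the person's left eye. No pair is ever emitted for a single detected
   eye, a closed-eyes frame, or an empty cabin.

## Worked example

```python
from eyegt import pipeline, synthgen

frame, truth = synthgen.render_frame(synthgen.scenario("open", seed=3))
result = pipeline.process_frame(frame, frame_id="demo")
print(result.status, result.face)
print(result.pair.left)
print(result.pair.right)
print(truth.left_pupil, truth.right_pupil)
```

prints

```
detected Box(lx=430, rx=850, ty=148, by=692)
EyeBox(ltx=682, lty=310, w=74, h=69)
EyeBox(ltx=528, lty=310, w=74, h=69)
(720, 340) (560, 340)
```

The face box tightly frames the rendered face; each 74×69 eye box (the
window size at 1280×800) contains the corresponding true pupil center.
The same flow from the shell:

```bash
eyegt synth --frames 4 --seed 5 --out frames --scenario mixed --drift 3 1
eyegt run --input frames --labels labels.csv
# processed=4 detected=2 no_face=0 no_pair=2 errors=0
eyegt visualize --frame frames/000000.png --labels labels.csv --out overlay.png
```

`labels.csv` holds one `frame_id,left_ltx,left_lty,right_ltx,right_lty,w,h`
row per detected frame plus the run summary; the mixed scenario's
closed-eyes and empty-cabin frames are correctly left unlabeled.

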