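# Methods

## Detection model and assumptions

The pipeline assumes in-cabin infrared imagery with a characteristic
intensity layering: the illuminated face is far brighter than the seat and
ceiling behind it, the eye region (iris/pupil plus shadow) is dark relative
to the surrounding skin, and the illuminator produces a small specular
glint on the cornea that is brighter than everything else in the eye. Every
decision the detector makes is taken on a three-level (black/gray/white)
quantization of some region, never on raw intensities, which removes
subject- and exposure-specific variation while preserving those contrasts.

### Dynamic double thresholds

For a region with histogram `h` and pixel count `N`, the trimmed range
`[left, right]` is found by accumulating `h` from each end until the
cumulative count first *touches or exceeds* `ceil(f·N)`, with tail fraction
`f = 0.17` by default. A small epsilon (1e-9) is subtracted before the
ceiling so that an exactly representable fraction (e.g. 17% of 10,000)
touches its bound instead of being pushed one unit past it by binary
floating-point error. `t`, `dt1`, `dt2` are integer floor-division
midpoints; pixel values are integers and no finer rounding rule is
meaningful. The tail fraction is exposed in configuration because the
resulting threshold is insensitive to it over roughly 5–20% on realistic
histograms (a property the test suite asserts on a skewed unimodal
histogram: `t` moves by well under 10% of the 0–255 range).

An important consequence used throughout: *any* unimodal region — a patch
of pure skin, say — is split by this rule into roughly one-third black,
one-third gray, one-third white, because the thresholds adapt to whatever
contrast is present. Filters therefore cannot rely on "skin quantizes to
white" in isolation; they rely on the *joint* pattern across sub-regions.

### Face area

The central band (30–70% of the width, full height) is quantized and
cleaned: vertical black runs and vertical gray runs shorter than 6.5% of
the height become white (removing glasses bars that would cut the head in
two), then horizontal white runs shorter than 7.8% of the width become
black (removing hair speckle that would drag the top edge upward). The
white 4-connected component at the band center — or, if the center pixel is
not white, the component(s) seeded by the nearest white pixel above and
below it, keeping the one with the smaller width/height ratio, ties going
to the upper — gives the face box. Components are computed with
`scipy.ndimage.label`, which is exactly equivalent to the recursive white-
pixel walk that defines the operation; the equivalence is asserted against
an independent BFS oracle in the tests.

Two deliberate properties:

* **Driver-absent guard.** A near-constant band (empty cabin) quantizes to
  speckle whose short runs are all converted to white by the cleanup,
  producing one component covering essentially the whole band. A candidate
  component covering more than 95% of the band area is therefore rejected,
  so empty-cabin frames yield "no face" rather than a full-frame box.
* **Tip erosion.** The white-run cleanup necessarily blackens the narrow
  tip rows of a convex face outline (any row narrower than 7.8% of the
  width). For the synthetic elliptical face this shifts the detected top
  and bottom edges ~8 px inward from the true ellipse bbox; the left/right
  edges are exact to within noise. This is a property of the algorithm,
  not an implementation artifact, and the tests encode it.

### Eye search and tracking

When the previous frame produced a pair, the search box is 26% W × 23% H
centered on the previous eyes' average position, computed verbatim from the
published averaging rule (left eye's top y with right eye's bottom y; the
symmetric variant is available behind `SearchParams.symmetric_avg_y` since
the asymmetry looks like a transcription slip, but the verbatim form is the
default). Otherwise the face area anchors a 35% W × 37% H box. Tracking
state resets after a single miss; the source and geometry of the box used
are recorded on every `FrameResult` so sequence behavior is observable.

Windows (5.8% W × 8.7% H, strides 1.1% W / 1.2% H) that would overhang the
search box are dropped rather than edge-snapped. All fraction-of-dimension
parameters become pixels as `max(1, floor(f·dim))`.

### Patch filters

* **Black-percentages rule.** Three regions, each with an inclusive
  acceptance range for its black-pixel percentage: the centered middle
  third (eye core) in [50, 100]%, the full patch in [15, 75]%, and the top
  25% band (forehead) in [0, 45]%. The published description fixes the
  *form* of this rule (three percentages feeding the score) but not its
  constants; these regions and ranges are this package's reconstruction,
  chosen from the tail-trimming arithmetic above: a unimodal skin patch
  lands near 33% black in every region (many standard deviations below the
  50% core floor at the 552-pixel core size), a face/background boundary
  patch is caught by the top-band ceiling, and a true eye core sits near
  100%. All constants are configurable. On synthetic frames the rule
  rejects ≈ 97% of raw windows.
* **Ratio map.** White and gray are first merged (only blackness matters).
  Each black pixel gets the lengths of the maximal horizontal and vertical
  black runs through it; the pixel turns white in the map when their ratio
  strictly exceeds 1.3, a fixed rectangularity constant. The score `r` is
  the white percentage of the map's middle third. `r` never rejects a
  patch; it only feeds the duel score.
* **Pupil-reflection check (mandatory).** Within the middle third, a
  4-connected white component passes if it has 4–24 pixels and the 3
  pixels extending outward from the midpoint of each bounding-box edge are
  all black (probes falling outside the patch fail). The pixel bounds are
  absolute counts, not resolution fractions, because the glint size is a
  property of the illuminator, and they are configurable for other sensor
  setups. The first passing spot in raster order wins.

### Duels and pairing

Overlap duels are implemented by ranking candidates by score (ties: upper,
then left, patch wins) and keeping each patch that overlaps no
better-ranked survivor; with distinct scores this is exactly the fixed
point of pairwise elimination in any duel order, which the tests verify by
permutation. Valid pairs satisfy `|Δy| ≤ floor(0.087·H)` and
`1.5·w ≤ |Δx| ≤ 3·w` on top-left corners; the best score-sum pair is
emitted with the greater-x member as the person's left eye.

## Synthetic frames

The generator renders, per `SceneSpec`: uniform dark background (10–40),
an elliptical face (150–220) in the central band, two dark elliptical eye
regions (30–70, semi-axes 28×16 px) whose centers are 160 px apart —
inside the valid interocular range at 1280×800 — each with a 3×3 glint
(250–255) when open, plus optional confounders: a dark glasses bar
(optionally with a small bright reflection, the known false-pupil failure
mode, flagged in the ground truth), hair speckle at the face top, a bright
surgical-mask band, and ±2 additive noise. Intensity bands were chosen so
the frame-level quantization maps background→black / face→white and the
patch-level quantization maps eye region→black with the glint as the only
white spot — i.e. the structure the real sensor produces.

Determinism: a frame is a pure function of its spec (seed included);
sequences derive frame `i`'s seed as `base + i` so geometry follows the
drift exactly while noise varies.

What the generator does *not* emulate: head rotation and perspective,
eyelid shapes and partial occlusion, intensity gradients across the face,
sclera/iris substructure, and glints distorted by gaze angle. Passing the
synthetic suite therefore demonstrates that the implementation realizes
the specified decision rules, not that the rules achieve any particular
precision on real recordings.

## Evaluation sizes and numerical choices

The shipped evaluation (tests and `scripts/acceptance.py`) uses 100
driver-present frames for recovery, 50 each for the empty-cabin and
closed-eyes guards, and pruning statistics over the same open frames
(~700 windows per frame); oracle equivalence checks use 500 random
histograms, 1000 random images and 200 random 40×40 grids. These sizes
give stable percentages (a single frame changes a rate by 1–2%) while the
whole evaluation completes in well under a minute.

Degenerate inputs: empty histograms and zero-area black-rule regions raise
errors; a constant region collapses all five thresholds to its value, so
only exact-value pixels are gray; multi-channel images are rejected rather
than converted; per-frame failures in a sequence are recorded as `error`
results (and reset tracking) instead of aborting the run.

## Known limitations

* The black-rule constants are a calibrated reconstruction (see above);
  on real recordings they would need re-calibration against a labeled
  sample before trusting the generated dataset.
* The glasses-reflection false-pupil failure mode is reproduced by the
  generator but not fixed by the detector (the published mitigation —
  whitening long horizontal black lines in the search area — is future
  work there too).
* Single-eye frames, near-duplicate-frame pruning of the output dataset,
  and nostril/mouth landmarks are out of scope.
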