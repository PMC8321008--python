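# Methods

## Setting

A depth camera (Kinect-v1 class: 640x480 at 30 fps, per-pixel
sensor-to-surface distance in mm, value 0 for an invalid measurement)
hangs from the ceiling above a dining table, roughly 3000 mm above the
floor with the table top 2100 mm from the sensor. Watching from above
preserves privacy — no face is ever visible — which makes the setup
suitable for ambient-assisted-living monitoring of eating behaviour.
The pipeline answers three questions per recording: when does the meal
start (SF) and end (EF), and how many food-intake actions (hand brought
to the mouth and held there) occur in between.

## Pipeline

### Preprocessing (`preprocess`)

1. **Hole filling** — zero-valued pixels take the value of their
   nearest valid pixel (Euclidean in pixel space, via a distance
   transform). The choice is deterministic, order-independent and
   idempotent; no smoothing is invented. An all-zero frame is an error.
2. **Background subtraction** — the person is *closer* to the ceiling
   sensor than the surfaces behind them, so foreground is
   `background − frame > min_diff_mm` (default 100 mm, a design choice:
   half the hand-gap threshold, comfortably above sensor noise).
   8-connected components above `min_area_px` (default 300 px at
   640x480) become `ForegroundBlob`s, largest first.
3. **Median denoising** — 5x5 window, edge-replicated borders. Depth
   sensors concentrate error at depth discontinuities (table edges,
   silhouette borders); the median suppresses exactly that speckle.
   The subtraction result is filtered, and hole filling precedes both.
4. **Sobel edges** — gradient magnitude thresholded in mm/px (the raw
   Sobel response divided by 8), used to delineate object borders such
   as the table perimeter.

### Point clouds (`pointcloud`)

Pinhole back-projection, sensor-centred right-handed coordinates with Z
down the optical axis: `X = (u−cx)·Z/fx`, `Y = (v−cy)·Z/fy`. Default
intrinsics are Kinect-v1-like (fx = fy = 585 px for 640x480) and scale
linearly with resolution; any real deployment should override them from
calibration. The head distance of a blob is its minimum depth — from
above, the closest surface of a person is the top of the head.

### Skeleton tracking (`som_tracker`)

The person is tracked by a 50-node self-organizing map with a fixed
topology: a 9-node head group (centre plus ring of 8), a 5x7 torso
lattice whose two front corners are replaced by shoulder attachments
(33 nodes), and two 4-node arm chains ending in the hand joints. The
three designated joints are Jhd (head centre), Jhl and Jhr (hands);
the other 47 nodes each anchor one local surface patch ("plane") of
the model — that is this implementation's reading of the model's 47
planes, which the original description counts but does not define.

Fitting is batch competitive learning, warm-started from the previous
frame: each sampled cloud point elects its nearest node (lowest index
on ties), and every node moves toward the neighbourhood-weighted mean
of its electorate with a Gaussian weight in topological hop distance.
Learning rate (0.6 → 0.2) and radius (1.5 → 0.8 hops) decay linearly
over the frame's iterations (4 by default). The floor of 0.8 hops is
deliberate: it keeps arm chains elastically attached to their
shoulders, so a chain that temporarily loses its hand (occlusion,
re-initialisation) is recaptured instead of wandering across the body.

Two guarantees are enforced structurally:

- **Monotone fit energy.** The fit energy is the mean node-to-nearest-
  cloud-point distance, evaluated on the frame's sampled points. An
  iteration whose update would increase it is rejected (the next,
  tighter-radius iteration still runs). Consequence: the energy after
  `fit_frame` never exceeds the energy before. The gate introduces a
  small hysteresis band — on sparse clouds the converged joints can sit
  a few tens of mm from the density-optimal position — which is far
  below the 200 mm decision thresholds downstream.
- **Bounding-box confinement.** Nodes are clipped to the cloud's
  axis-aligned bounding box inflated by 100 mm; projection onto a
  convex set containing the points cannot increase any node-to-point
  distance, so the clip never violates the energy guarantee.

The cloud is capped at `subsample` points per frame (default 2000,
seeded; `None` fits the full cloud). Model initialisation is purely
geometric: head ring at the cloud's highest region, torso lattice
spanned behind it along the facing direction, arm chains reaching
forward. Facing is estimated once at the start frame as the mean
direction of the farthest-in-XY points (the hands on the table) and
held — the widest principal axis would give the shoulder line instead.

**Joint fusion and reset.** A hand node collapsing onto the head is
detected as a head-hand distance below 200 mm (or 300 px in image
space, selectable) sustained for `fusion_frames` consecutive frames
(default 150 = 5 s at 30 fps); the model is then re-initialised on the
current cloud, which separates the joints immediately. Inside
`track_sequence` the reset is joint-preserving: the chain of a hand
that was *not* fused keeps its fitted nodes, because two freshly placed
chains would compete for whichever single hand is visible and can swap
sides permanently. The standalone `reset_model` operation is the full
re-initialisation and is idempotent.

### Meal segmentation (`session_detector`)

A short-circuiting four-step checklist per frame: person blob present →
head midpoint within the table box expanded by `dist_px` (45 px,
inclusive boundary) → sitting test → at least one hand blob on the
table (foreground over the table mask, 0 < height above table top <
200 mm, area > 300 px).

The sitting test compares the current head distance with the *standing
baseline*, the running minimum of head distance over frames not
classified as sitting. Two dialects exist because the source material
supports both readings; the default follows the worked arithmetic
(threshold anchored on the seated reading):

- `threshold-on-seated` (default): sitting iff
  `current × (1 − ratio) ≥ baseline`; a 1700 mm seated reading at
  ratio 0.3 implies a 1190 mm standing threshold.
- `threshold-on-standing`: sitting iff `current ≥ baseline × (1 + ratio)`.

SF is the first frame passing all four checks. EF is the last frame
the checks held before a confirmed departure — the person absent or
outside the expanded table box for `absence_frames` (default 90 = 3 s;
the confirmation lag prevents noise-induced splits) — or before the end
of the file. A genuine departure followed by re-seating opens a second
(SF, EF) segment of the same meal. Segments shorter than 30 frames are
discarded as flicker. A sequence that *starts* with the subject already
seated (no standing baseline can ever form) is treated as seated from
frame 1 if presence, table proximity and hands-on-table all pass there;
that mode ends when the head distance drops by the ratio fraction below
the running seated reference, which then seeds the baseline.

Acquisition files roll over every 27000 frames (15 min at 30 fps);
`rollover` splits sequences accordingly.

### Action counting (`intake_counter`)

Per hand, the head-hand distance series is scanned for maximal runs
below `action_dist_mm` (200 mm). Runs separated by less than
`refractory_frames` (30) merge — a tracker reset produces exactly such
a one-frame interruption — and merged runs of at least
`dwell_min_frames` (150 = 5 s) count as one action. Overlapping
left/right events (≥ 50% of the shorter) merge into a single
two-handed event. Absent frames break runs.

The 5 s action dwell and the 5 s fusion window coincide by
construction. Resolution: an action is counted as soon as its run
reaches the dwell, after which a reset is harmless (the refractory
merge absorbs it); the two windows are independently configurable, and
the synthetic study described below runs the tracker with a 7 s fusion
window so that a correctly tracked bite does not trigger a model reset
mid-action — genuine stuck joints still do.

### Evaluation (`metrics`)

AE = |x̂ − x|, MAE = mean AE, MRE% = 100 × mean(|x̂ − x| / x). The
relative error takes the absolute value per term: every reference
summary value is non-negative and the manual start-frame row
reproduces only under that reading. A zero truth raises (frame indices
are 1-based, so the bundled data never triggers it). The harness
aligns automatic / manual SetParam tables and per-test action counts
with ground-truth annotations by test number and emits the familiar
MAE / MRE rows. The bundled 33-test reference tables reproduce their
reported start-frame rows (SFA 10.636 / 5.537%, SFM 8.939 / 54.410%)
and action row (0.424 / 5.044%) to three decimals. The end-frame rows
are computed but are known not to match the reported summary from the
per-test values themselves (they match only if one
ground-truth EF entry, test 24, reads 5330 rather than the printed
5390 — an apparent typo); the discrepancy is reported, not corrected.

## Synthetic scenes (`synthetic_scene`)

No depth recordings accompany the bundled reference tables, so
the generator is the package's testbed. It renders a 2.5-D person —
flat head disc over shoulder/torso ellipse, capsule arms, hand discs —
entering the view, walking to the table, sitting (head-to-sensor
distance multiplied by 1 + `sit_drop`), resting both hands on the
table, and lifting one hand to the mouth for scripted windows. Sensor
artefacts: zero-mean Gaussian mm noise plus hole dropout concentrated
within 2 px of depth discontinuities (> 200 mm jumps), which is where
structured-light sensors genuinely fail. The `SENSOR_NOISE` preset
(sigma = 10 mm, 30% dropout) represents a realistic acquisition; the
noise amplitude is a stated choice, not a measured one. Defaults are
clean (noise 0) so geometric contracts are exact.

Deliberate modelling choices, and what they imply about test coverage:

- `sit_drop` defaults to 0.45. The worked seated/standing example in
  the source (1190 mm standing, 1700 mm seated) implies a real seated
  increase of ~43%, and the default sitting rule only fires when
  `sit_drop > ratio/(1−ratio) ≈ 0.43`; a smaller drop (0.35, say)
  would render every default scene undetectable by the rule it is
  meant to exercise. Configurable downward for negative tests.
- Scripted subjects sample heights in 1830–1970 mm. With the table top
  900 mm above the floor and ratio 0.3, shorter subjects cannot drop
  their head far enough while keeping shoulders and forearms above the
  table plane — the same population for which the original system
  reported sitting-test failures. Short subjects remain constructible
  and reproduce that failure mode.
- The at-mouth hand sits 120 mm forward of the head centre and 85 mm
  below the head top (3-D gap 147 mm): a hand directly under the head
  would be invisible to a ceiling sensor, so the visible crescent
  protrudes past the head rim.
- The person model has no legs, no chair physics and flat (not domed)
  surfaces; passing tests demonstrate the pipeline's logic on faithful
  depth silhouettes, not robustness to clothing, reflective surfaces,
  multiple people or real sensor bias fields.

## Problem sizes

End-to-end tests and the acceptance study render scenes on a 160x120
grid with intrinsics and every pixel threshold scaled by 1/4 from
their 640x480 definitions (areas by 1/16); millimetre geometry is
unchanged. The recovery study runs ten scenes of roughly 1000–4300
frames with 3–15 scripted actions each at `SENSOR_NOISE`, tracking at
most 600 cloud points per frame — about 20k frames in total, chosen to
keep a full study in the minutes range on a single core. Tracking at
full resolution and `subsample=None` reproduces the same behaviour
more slowly.

## Known limitations

- The fusion threshold's image-space variant (300 px) is selectable
  but the metric-space 200 mm form is the default; the two are only
  loosely equivalent and the stated px↔mm correspondence does not
  follow from pinhole geometry at these depths.
- The energy-gated batch fit has a hysteresis band (see above);
  joint positions carry a static bias of order 10–25 mm on sparse
  clouds.
- Orientation is estimated once per segment and held; a subject who
  rotates substantially mid-meal would degrade arm-chain assignment.
- One person per scene; no multi-person arbitration.
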