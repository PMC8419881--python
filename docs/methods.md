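# Methods

## Data model

An annotation panel is an A × M grid of `ImageAnnotation`s (A annotators,
M images). Each cell holds zero or more simple polygons, each labeled with
one of the five ICA layers (IR, CBB, SS, TM, C in anatomical order, inner
to outer). Polygons of one annotator must not overlap at the pixel level;
several polygons may share one label (split regions) and their pixel sets
are unioned. Everything outside the polygons is NA — "no statement" — and
every analysis is designed so that NA can never masquerade as either
background or disagreement.

Coordinates are pixel units, origin top-left, x rightward, y downward; the
pixel (col, row) has its center at (col + 0.5, row + 0.5). VIA projects do
not record image dimensions, so these travel in the dataset manifest (or in
`width`/`height` file attributes, which this package writes on export so
its own projects round-trip).

## Rasterization

A pixel belongs to a polygon iff its center lies inside under the even-odd
rule. Centers exactly on an edge are resolved by a top-left tie-break: the
test point is perturbed by +ε (ε = 1e-7 px) in x and y before the
crossing-number test. This is deterministic, matches scanline rasterizers,
and makes abutting polygons that share an edge partition their pixels
cleanly (verified against an independent geometric engine in the tests).
There is no canonical sub-pixel rule for hand-traced clinical polygons;
any reasonable choice perturbs areas by at most a one-pixel-wide boundary
band, which the tests bound explicitly (raster area of a convex polygon is
within its perimeter of the continuous area).

Vertices dragged outside the image are clamped to the image rectangle with
a warning rather than rejected; a polygon that encloses no pixel center is
dropped with a warning at rasterization (it cannot influence any pixel-wise
statistic). A pixel claimed by two *different* labels is a hard error;
non-overlap is additionally checkable up front via `validate_non_overlap`,
which reports every polygon pair sharing pixel centers.

## Frequency

`annotation_frequency` counts, per annotator and layer, the images
containing at least one polygon of that layer — existence, not geometry or
polygon multiplicity, because the quantity of interest is the annotator's
confidence that the layer is identifiable at all. The per-layer spread is
summarized as the maximum pairwise percent difference with the **larger
count of the pair as denominator**:
|c_a − c_b| / max(c_a, c_b) × 100. The denominator convention is a design
choice (a mean-based variant is equally defensible); it is recorded in the
output and trivially recomputable from the exported counts. All argmax
pairs are reported when ties occur; with every count zero the measure is
undefined and flagged rather than forced to a number.

## Consensus

For layer ℓ and threshold n, with k = number of annotators labeling a
pixel ℓ and d = number labeling it a *different* layer (NA never counts
toward d):

| condition        | category          |
|------------------|-------------------|
| k = 0            | background        |
| k ≥ n            | consensus (+1)    |
| k < n and d ≥ 1  | disagreement (−1) |
| k < n and d = 0  | ignored (0)       |

The three categories partition the union of the layer's masks; n = 1 yields
the union, n = A the strict intersection.

The curve normalization is genuinely ambiguous — "consensus over annotated
pixels" and "ignore the ignored region" conflict whenever pixels move into
the ignored category at high n — so all three readings are implemented and
exported:

* `exclude-ignored` (default): c / (c + d). Ignored pixels affect neither
  side, so the curve moves only when actual label conflicts exist; this is
  the only reading under which abstention is fully neutral, and the
  NA-insensitivity property (relabeling a conflicting pixel to NA can only
  raise the ratio) holds by construction.
* `union-denominator`: c / u.
* `not-disagreeing`: (c + i) / u.

Counts are pooled over the dataset before the ratio (one curve per layer);
per-image curves are available for diagnostics. No probabilistic label
fusion (STAPLE-style) is attempted — the consensus is purely counting-based.

## Pairwise agreement

`confusion_matrix` tallies the 5×5 counts over pixels labeled by both
annotators; NA on either side excludes the pixel. Per-image matrices for a
pair are summed (**pooled** scope, the default — more stable with layers
that appear in few images) before metrics are computed; a per-image scope
is a flag away, and the two genuinely differ (a constructed example in the
tests shows pooled precision 0.91 vs a 0.55 per-image average). Dice is
computed as the harmonic mean of precision and sensitivity exactly as
defined, with the count identity 2TP/(2TP+FP+FN) kept as a test-side
cross-check.

Undefined metrics (layer absent from the relevant denominator) are NaN,
excluded from means/SDs, and counted in `n_undefined`; imputing 0 would
selectively drag down exactly the sparse layers (SS, CBB) whose agreement
is the point of the analysis. SDs are sample SDs (ddof = 1), NaN when
fewer than two defined values exist; `n_comparisons` makes the support of
every summary cell explicit.

Useful diagnostic signatures, all asserted in the tests: precision of
(a vs b) equals sensitivity of (b vs a); Dice is symmetric in the pair; an
annotation strictly inside the reference (rest labeled, not NA) gives
precision 1 with sensitivity < 1 ("thinner but centered"); a displaced
band depresses precision and sensitivity together.

## Synthetic panels

The generator emulates the statistical structure of a clinician panel, not
its appearance:

* **Geometry** — five horizontal bands below an unassigned top margin.
  Band geometry keeps the ordered-layer adjacency structure (the only
  geometric fact the statistics depend on) while admitting closed-form
  checks; curved sector arcs would add realism the label-set statistics
  cannot see. Default fractions of the image height: IR 0.30, CBB 0.10,
  SS 0.05, TM 0.15, C 0.30 (margin 0.10) — SS thinnest and CBB second, the
  layers that are hardest to trace in practice.
* **Boundary jitter** — per annotator and boundary, control-point
  displacements ~ Normal(bias, sigma²) at 8 knots across the width,
  PCHIP-interpolated into a smooth curve; default sigma 3 px on a 320×240
  grid (≈ 1 % of image height, a plausible hand-tracing scale). Adjacent
  bands of one annotator share the identical jittered boundary and curves
  are order-clamped (never crossing), so within-annotator overlap is
  impossible by construction; a band clamped to zero height everywhere is
  a simulation error.
* **NA from two mechanisms** — lateral truncation to a centered window
  (default 85 % of the width, emulating vignetting/defocus periphery) and
  whole-layer omission with per-layer defaults IR 0, CBB 0.15, SS 0.25,
  TM 0.05, C 0.05, mirroring that the iris root is essentially always
  identifiable while the scleral spur is most often skipped.
* **Scale** — default panels are 20 images × 5 annotators at 320×240 px,
  a 4× linear downscale of the 1280×960 source format that preserves all
  band proportions; analyses are resolution-invariant ratios, and tests
  use still smaller grids (≤ 160×120) chosen for thorough property
  checking at interactive speeds.

With zero jitter, zero bias, full extent and zero omission, every
annotator's label map equals the ground truth on annotated pixels, which
yields the exact perfect-agreement limit: flat unit consensus curves, all
Dice 1, all SDs 0, equal frequencies. Two straight bands of height h
offset by b have Dice (h − |b|)/h, matched by simulation to within 2/h
(discretization); mean Dice decreases strictly with jitter sigma and thin
bands degrade fastest, reproducing the qualitative IR/TM/C ≫ CBB/SS
agreement ordering.

What the generator does **not** emulate — curved anatomy, appositional
angle closure (layer absence arises only via omission, never occlusion),
image texture, or annotator-specific systematic styles beyond
bias/extent/omission — bounds what passing tests show about clinical data:
they verify the *analysis machinery* exactly, not the clinical magnitudes,
which depend on the real panel.

## Numerical and I/O choices

* Rasterization tie-break ε = 1e-7 px; vertices are stored as floats and
  JSON round-trips preserve them to precision.
* Confusion counts and region sizes are exact integers; only final ratios
  are floating point.
* CSV exports use a fixed float format so identical runs are
  byte-identical; `run_metadata.json` records the config hash, package
  version and seed needed to regenerate any table.
* All randomness flows from a single `numpy` Generator seeded by
  `SimConfig.seed` with a fixed draw order, so panels are bit-reproducible
  across platforms.

## Known limitations

* The percent-difference denominator and the consensus normalization each
  have defensible alternatives; both are configurable, and the exports
  carry enough raw counts to recompute any variant.
* Pooled-scope SDs summarize only A − 1 values per cell; with A = 5 they
  are coarse, and the per-image scope trades stability for support.
* The simulator's parameters are stand-ins chosen for realism, not
  calibrated to any clinical panel; synthetic headline numbers should be
  read as illustrations of the pipeline, not estimates of clinical
  agreement.
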