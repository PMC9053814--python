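# Methods

`blebquant` quantifies plasma-membrane blebbing in time-lapse microscopy of
single cells, aimed at the fast-amoeboid (leader-bleb-based) migration
literature, where a mechanically confined cell either migrates behind one
large stable bleb (leader mobile, LM), holds a leader bleb without moving
(leader non-mobile, LNM), or shows only small transient circumferential
blebs (no leader, NL). The toolkit is a headless re-engineering of the
interactive workflow common in this field: segment the cell, remove the
user-defined cell body, and measure what remains — the blebs — frame by
frame.

## Pipeline model

The analysis is a deterministic function of the movie, the per-frame
cell-body outline, and a small set of parameters:

1. **Reduction** — a multi-dimensional TIFF is reduced to one channel and
   one Z plane (selected slice, maximum- or mean-intensity projection),
   and calibrated to µm/pixel and min/frame. Uncalibrated inputs default to
   1 µm/pixel and 8 min/frame with a logged warning; 8 min/frame is the
   sampling interval at which the 5-frame persistence rules below equal
   40 minutes.
2. **Tracer editing** — optional exclusion polygons whose interiors are
   replaced with the frame's modal background intensity, the headless
   equivalent of erasing debris and neighbouring cells before
   thresholding.
3. **Segmentation** — a global histogram threshold per frame (default) or
   propagated from frame 0, then hole filling, optional morphological
   opening (disk radius in px), and size exclusion (keep-largest by
   default). The result is the whole-cell mask, one 8-connected component
   per frame.
4. **Compartment split** — all_blebs = whole_cell ∖ body;
   cell_body = whole_cell ∖ all_blebs. These are exact set operations, so
   per frame the body and the blebs partition the cell pixel-for-pixel, and
   area is conserved by construction. Sub-threshold gaps between a bleb and
   the body are not bridged; orphan components simply appear as blebs.
   The largest bleb per frame (ties to the lowest label in scan order,
   logged) is the per-frame proxy for the leader bleb.
5. **Measurement, tracking, classification** — descriptor battery per
   compartment per frame, per-cell means, centroid trajectory, greedy
   overlap tracking of blebs, and the LM/LNM/NL label.

There is no randomness anywhere on this path; repeated runs produce
byte-identical CSVs (numbers are serialized with 6 significant digits to
make byte-identity well defined).

## Thresholding

Otsu is implemented in-package as an exhaustive maximization of
between-class variance over a 256-bin histogram spanning the frame's
intensity range (vectorized cumulative moments; ties resolve to the lowest
cut). The unit tests hold it equal to a brute-force python-loop oracle on
random 8-bit frames. The other six methods (mean, li, triangle, yen,
isodata, minimum) delegate to `skimage.filters` on the same 256-bin
histogram, so results are independent of camera bit depth. Which method an
interactive user would have picked from a preview is replaced by
`--report-all-methods`, which writes every method's frame-0 mask for
offline choice.

Per-frame thresholding is the default because intensity drift
(photobleaching) over hours of imaging shifts a frame-0 threshold off the
later frames; first-frame mode is retained for parity with the interactive
workflow. Constant frames are an error naming the frame index.

## Shape descriptors

For a region of area `A` (µm², pixel count × pixel size²) and perimeter
`P`:

| descriptor | definition | range |
|---|---|---|
| circularity | 4πA/P², clamped to ≤ 1 | (0, 1] |
| aspect ratio | M/m of the fitted ellipse | ≥ 1 |
| roundness | 4A/(πM²) | (0, 1] |
| solidity | A / convex-hull area | ≤ 1 + ε |

The fitted ellipse takes its orientation and axis ratio from second-order
central moments (each pixel treated as a unit square, adding the 1/12
self-moment so single-pixel and thin regions stay finite) and is then
scaled so the ellipse area πMm/4 equals `A` — the de-facto standard in
interactive image analysis, under which roundness is exactly 1/aspect-ratio.

**Perimeter** uses the 4-direction Crofton estimator
(`skimage.measure.perimeter_crofton`). The choice is deliberate: chain-code
estimators (edge step 1, diagonal step √2) systematically overestimate
smooth digital contours by 5–7%, which biases circularity of a radius-50
digital disk down to ≈ 0.90; the Crofton estimator measures the same disk
at 0.992. Measured circularity is an estimate that converges to the
continuous value as the object is better resolved; it is quantitatively
trustworthy only for objects more than a few tens of pixels across, which
is why the test suite checks resampling stability of circularity on
resolved smooth shapes but of the moment- and hull-based descriptors
(which are genuinely resampling-stable) on arbitrary blobs.

**Solidity** divides the pixel area by the exact polygon area of the convex
hull of pixel *corner* points (each pixel contributes its four corners).
This makes solidity exact for polyominoes — a plus-shaped pentomino scores
5/7 — where hull-image pixel counting would be ambiguous at the cut
corners.

Empty regions produce no record (logged); they never emit NaN rows from
`measure`. Bleb-free frames do appear in the per-image table as
`bleb_count = 0` rows with undefined shape columns.

**Per-cell averages** are unweighted means over frames. Bleb shape
descriptors average only over frames that contain at least one bleb (the
shape of nothing is undefined); `bleb_count` and the percent-of-cell-area
measures average over all analyzed frames, with bleb-free frames
contributing zeros. Both denominators are reported as `n_*` columns, and
`include_blebless_in_shape_means=True` switches to zero-filled means for
sensitivity analyses.

## Bleb tracking and lifetimes

Blebs are linked frame-to-frame by greedy maximum pixel overlap: candidate
pairs ranked by overlap, matched one-to-one, accepted when
overlap / min(area_prev, area_next) ≥ `link_min_overlap` (default 0.5).
Unmatched components start new tracks; tracks end when unmatched. There is
**no gap closing**: at minutes-per-frame sampling, blebs genuinely retract
and reform between frames, so a one-frame absence is treated as two blebs.
Curvature-based bleb trackers need second-scale sampling and are not
applicable here. Lifetime is `frames × frame_interval`, so a track
spanning 5 frames at 8 min/frame has lived 40 minutes.

## Phenotype classification

Two predicates, each a 5-frame persistence rule (40 min at the reference
sampling), combine into the label:

* **has_leader_bleb** — some track survives ≥ `persistence_frames`
  (default 5) with mean area ≥ `leader_area_frac` (default 0.10) of the
  mean whole-cell area over the same frames.
* **is_mobile** — some window of `persistence_frames` consecutive intervals
  has mean speed ≥ `speed_min` (default 0.25 µm/min) and directionality
  ratio (net displacement / path length) ≥ `dir_min` (default 0.5).

LM = both, LNM = leader only, NL = no leader (mobility alone never makes a
leader phenotype). Fewer than 5 analyzed frames yields `undetermined`.
The speed floor is half the ≈ 30 µm/h (0.5 µm/min) typical of fast
amoeboid migration — permissive enough to catch slow movers while
rejecting centroid jitter; the directionality floor encodes "directionally
persistent" as at-least-half-ballistic over the window. All four
parameters are exposed on the CLI; the defaults are the package's
operationalization of field practice, since prose descriptions of
"directionally persistent migration" and "large stable bleb" do not pin
down numbers.

Speeds are centroid displacements divided by the frame interval;
`zero_origin` provides the standard plot-of-origin transform (all
trajectories translated to start at (0, 0)).

## Synthetic movies

The generator renders an elliptical cell body (default semi-axes
12 × 9 µm, i.e. a ≈ 340 µm² cell, the scale of a confined melanoma cell)
with circular blebs attached at fixed body angles, at 0.5 µm/pixel,
8 min/frame, 10 frames, cell/background intensities 120/20, and additive
Gaussian noise with σ = 5% of that contrast. Presets:

* `LM` — one permanent 10 µm leader bleb (≈ 25–30% of cell area), linear
  motion at 0.5 µm/min toward the bleb. The bleb is deliberately large
  relative to the per-frame displacement (4 µm) so that its frame-to-frame
  overlap stays above the linking threshold, as real leader blebs do.
* `LNM` — the same leader bleb, no motion.
* `NL` — six 2.5 µm blebs with 1–2-frame lifetimes at randomized angles
  and birth frames.
* `apoptotic_like` — eight 3 µm blebs, 1–2-frame lifetimes (highly dynamic
  blebbing).
* `low_confinement_like` — two long-lived, radially elongated 4 µm blebs.

Truth masks are the noise-free rasterizations with the same set-algebra
semantics as the pipeline (bleb pixels inside the body ellipse belong to
the body); truth tracks and the truth phenotype are derived from the scene
parameters directly, not by running the segmentation under test. A single
integer seed drives one `numpy.random.default_rng` for preset geometry and
noise, so a seed fully determines the movie.

What the generator does **not** emulate: textured fluorescence (cortical
enrichment, gradients), membrane retraction dynamics within a frame,
cell-shape deformation other than rigid translation, out-of-focus light,
or multiple interacting cells. Passing the closed-loop tests therefore
shows that the measurement chain is self-consistent and robust to additive
noise at realistic contrast — not that segmentation is robust to every
real-microscopy artifact; for difficult data the exclusion-ROI editing and
threshold-method choice exist precisely because no global threshold is
universally right.

## Numerical and degenerate-input choices

* Pixel coordinates are 0-based (row, col); polygons fill by the even-odd
  rule plus their boundary trace.
* Foreground connectivity 8, hole connectivity 4.
* Largest-bleb ties break to the lowest label id and are logged.
* Empty frames: size exclusion warns and returns empty; measurement skips;
  classification treats missing blebs as "no leader".
* Thin/degenerate regions: the 1/12 moment correction keeps aspect ratio
  finite and ≥ 1.
* CSV floats use 6 significant digits; masks round-trip losslessly through
  8-bit 0/255 TIFF.

## Problem sizes used in the validation suite

The shipped checks run on 24–32 px oracle frames (200 for thresholding,
100 for mask algebra), radius-50/100 digital shapes, and 192 px, 10-frame
synthetic movies (60 movies for phenotype recovery, 20 for the lifetime
contrast) — sizes at which every oracle comparison is exact and the whole
suite completes in well under a minute of CPU apiece.

## Known limitations

* Global thresholding only; no adaptive/learned segmentation, no watershed
  splitting of touching cells (handled instead by per-cell exclusion ROIs).
* Body definition is an explicit input (ROI or mask), not auto-detected.
* No gap closing in bleb tracking (by design, see above); lifetimes are
  lower bounds when a bleb drops below threshold for a single frame.
* No fluorescence-intensity statistics, Feret diameters, or curvature
  measures.
* Phenotype thresholds are heuristics in physical units; they require a
  calibrated movie and should be re-examined for cell types much smaller
  or slower than confined melanoma cells.
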