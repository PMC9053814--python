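# blebquant

Headless, scriptable quantification of **blebbing cells** in time-lapse
microscopy.

When cells are mechanically confined they can switch to fast amoeboid
(leader-bleb-based) migration: the cell moves behind one large, stable
plasma-membrane bleb. Quantifying this behaviour means segmenting the cell
on every frame, separating the blebs from the cell body, measuring shapes,
tracking blebs through time, and deciding whether each cell is **leader
mobile (LM)** — forms a leader bleb and migrates — **leader non-mobile
(LNM)** — forms one but stays put — or **no leader (NL)**. Doing that by
hand, frame by frame, is slow and poorly reproducible. `blebquant` does it
as a deterministic batch pipeline for anyone analysing confined-cell,
apoptosis, or other blebbing assays.

## What it computes

Per frame and per compartment (whole cell, cell body, all blebs, largest
bleb):

* area *A* (µm²), perimeter *P* (µm, 4-direction Crofton estimator)
* circularity 4π*A*/*P*² (≤ 1), solidity *A*/*A*<sub>convex hull</sub>
* fitted-ellipse axes *M*, *m* (moment orientation, area-matched scaling):
  aspect ratio *M*/*m*, roundness 4*A*/(π*M*²) = *m*/*M*
* bleb count, % of cell area for all blebs and for the largest bleb

Per cell: frame-averaged descriptors, centroid trajectory with
instantaneous speeds |Δ**x**|/Δ*t* (µm/min) and plot-of-origin transform,
bleb tracks by greedy pixel-overlap linking with lifetimes (frames ×
frame interval), and the LM/LNM/NL label from two 5-frame (40 min at
8 min/frame) persistence rules — a bleb track holding ≥ 10% of cell area,
and a window with mean speed ≥ 0.25 µm/min at directionality ratio ≥ 0.5.

A synthetic-movie generator (`blebquant.synthetic`) renders calibrated
movies of an elliptical cell with attached blebs — presets for LM, LNM,
NL, apoptotic-like, and low-confinement-like dynamics — together with
ground-truth masks, tracks, and phenotype, so the entire pipeline is
testable closed-loop without real data. See `docs/methods.md` for the full
model and parameter rationale.

## Worked example

Render a leader-mobile synthetic cell, then analyse it (the truth body
mask stands in for the per-frame "circle the cell body" input — with real
data you supply polygon ROIs as ImageJ `.roi`/`.zip` or the package's JSON
format):

```sh
blebquant simulate --preset LM --seed 7 --out demo
blebquant run --input demo/LM_seed7.tif --out demo/analysis --name demo \
    --body-roi demo/LM_seed7_truth_Cell_body.tif
```

which prints

```
wrote LM_seed7 (LM) to demo
cell1: LM (leader=True, mobile=True)
```

— the pipeline recovered the generated phenotype: a leader bleb was found
(a bleb track persisting ≥ 5 frames above 10% of cell area) and the cell
moved directionally fast enough. `demo/analysis/` now contains the four
compartment mask stacks (`demo_cell1_Whole_cell.tif`, `..._All_blebs.tif`,
`..._Cell_body.tif`, `..._Largest_blebs.tif`), per-frame measurements,
trajectory, bleb tracks, and one summary row:

```
cell_id  largest_bleb_area_um2  largest_bleb_aspect_ratio  whole_cell_area_um2  whole_cell_roundness  whole_cell_pct_leader_bleb
  cell1                189.825                    1.68978              528.725              0.631462                     35.9023
```

The largest bleb averages ≈ 190 µm², 36% of the ≈ 529 µm² cell — a
textbook leader bleb. The trajectory CSV shows the migration the label
rests on (≈ 0.5 µm/min ≈ 30 µm/h, the fast-amoeboid regime):

```
 frame  t_min    x_um    y_um  speed_um_min
     0      0 56.8900 57.5726          NaN
     1      8 54.0705 54.7457     0.499071
     2     16 51.2626 51.9353     0.496598
```

and the tracks CSV contains a single bleb track alive for all 10 frames
(lifetime 80 min). The same analysis runs from Python via
`blebquant.run(RunConfig(...))` or, stage by stage, with
`segment_whole_cell` / `remove_body` / `analyze_cell`.

Other entry points: `blebquant measure --masks ...` (morphometrics only on
pre-made masks) and `blebquant run --resume from_whole_cell` (restart
partway from saved masks). Thresholding, cleanup, and classification
parameters are all flags; see `blebquant run --help`.

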