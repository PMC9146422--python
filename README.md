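# scratchtrack

Bounding-box cell tracking and wound-repair analysis for **low-resolution,
low-framerate, high-density** scratch-assay time-lapse movies.

## The problem

In an in vitro scratch (wound-repair) assay, a confluent epithelial
monolayer is mechanically wounded and imaged over time; the cells at the
wound margins — the *leading-edge cells* — migrate to close the gap. Drug
screens for compounds that modulate epithelial repair (e.g. an Akt inhibitor
delaying migration, a ROCK inhibitor accelerating it) quantify that
migration from single-cell trajectories. High-throughput imaging makes
manual tracking infeasible, and the data are hostile to generic trackers:
~1.33 µm/px resolution (every cell a "small object", < 32 px), 30-min frame
intervals (0.03 frames/min, so a cell can move farther between frames than
the distance to its neighbours), and more than 1000 cells per 1620 × 1176 px
frame.

`scratchtrack` implements the full analysis chain for this regime:

1. **Detection** — cells as axis-aligned bounding boxes. Detectors are
   pluggable (register any callable; e.g. a trained neural detector); a
   classical blob detector (smoothing → relative threshold → connected
   components → watershed splitting) is built in so the pipeline runs
   without any trained model.
2. **Tracking by detection** — per-frame detections are linked by solving a
   linear assignment problem on `1 − affinity`, where the affinity is a
   convex combination of two appearance features (normalised
   cross-correlation, histogram intersection) and four motion features
   (gated centroid distance, IoU, size ratio, directional consistency).
   Multi-stage tracklet association then closes detection gaps with
   progressively looser temporal gates (motion-extrapolated, interpolated
   entries flagged), and *tracklet cleaving* cuts implausible jumps so
   mislinked fragments re-associate correctly.
3. **Wound analysis** — the two leading-edge rows are found automatically
   from the vertical cell-density profile (plateau median, sub-threshold
   band around the density minimum, raw-count boundary refinement), and
   leading-edge tracks are sampled (default n = 20 per experiment).
4. **Migration metrics** — per track: Euclidean distance *d* = s‖c_T − c_1‖,
   accumulated distance *D* = s Σ‖c_{t+1} − c_t‖, velocity *D*/hours,
   directionality *d*/*D*, Y-forward migration index (signed wound-ward net
   displacement / *D*), and end-point angle (wound-ward direction ↦ 90°).
   Conditions are compared per metric with two-sample
   Wilcoxon–Mann–Whitney tests (exact permutation enumeration for
   n + m ≤ 20, tie-corrected normal approximation otherwise).
5. **Evaluation** — CLEAR-MOT (MOTA = 1 − (FP + FN + IDSW)/n_gt, identity
   switches, track-recovery fractions) against MOTChallenge-format ground
   truth.
6. **Simulation** — a seeded scratch-assay simulator (two monolayers, wound
   band, condition-dependent leading-edge speeds, rendered blob frames,
   corruptible detections) provides ground truth for every stage.

I/O speaks MOTChallenge det/gt/track files, ImageJ Manual Tracking TSV,
TIFF/PNG/JPEG frame folders, CSV metric tables and an HTML report.

## Worked example

Simulate a delayed (Akt-inhibited) and an accelerated (ROCK-inhibited)
experiment, analyse both, and evaluate tracking against the simulator's
ground truth:

```sh
scratchtrack simulate --preset delayed     --seed 7 --width 500 --height 480 \
    --frames 8 --wound 120 360 --spacing 36 -o delayed/
scratchtrack simulate --preset accelerated --seed 8 --width 500 --height 480 \
    --frames 8 --wound 120 360 --spacing 36 -o accelerated/
scratchtrack analyze delayed/ accelerated/ -o results/ --n-sample 20
scratchtrack track -d delayed/det.txt -o hyp.txt
scratchtrack evaluate --gt delayed/gt.txt --hyp hyp.txt
```

which prints

```
simulated 112 cells over 8 frames -> delayed
simulated 112 cells over 8 frames -> accelerated
report -> results/report.html
112 tracks -> hyp.txt
MOTA 1.0000 (n_gt 896, FP 0, FN 0, IDSW 0, complete-track recovery 1.000)
```

`results/migration_metrics.csv` holds one row per sampled leading-edge
track; averaging it per condition gives

```
             euclidean_distance  velocity  directionality  y_fmi
accelerated              140.22     40.14            1.00   1.00
delayed                   29.59      8.89            0.95   0.95
```

i.e. accelerated leading-edge cells covered ~140 µm net (40 µm/h mean
speed) versus ~30 µm for the delayed condition, both migrating essentially
straight toward the wound (directionality ≈ y-FMI ≈ 1). In
`results/group_comparisons.csv` the distance, velocity and directionality
metrics separate the two conditions at p ≈ 7 × 10⁻⁸ (Wilcoxon–Mann–Whitney,
n = 20 per group), while the end-point angle does not (p ≈ 0.26) — both
conditions head wound-ward, they just differ in how far and how fast.
`results/report.html` bundles the tables with common-origin trajectory
plots and the frame-1 leading-edge overlay. The `MOTA 1.0000` line confirms
that on this unambiguous movie the tracker reproduced every ground-truth
trajectory without an identity switch.

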