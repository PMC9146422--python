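# Methods

This note documents the models, algorithms and design choices behind
`scratchtrack`, in the order the pipeline runs them.

## Coordinate and data conventions

Continuous pixel coordinates, origin at the image's top-left, y increasing
downward. A bounding box is the closed rectangle `[x_min, x_max] ×
[y_min, y_max]`; width is `x_max − x_min`, matching MOTChallenge
width/height semantics. Frames are 1-based. Physical metadata — pixel size
(µm/px) and frame interval (min) — must always be supplied explicitly
(sidecar `sequence.json` or CLI flags); defaulting them silently would
corrupt every µm/h quantity downstream.

Object-size classes use the MOT small-object convention compared on box
*area*: below 32² px² is small, above 96² px² large, medium otherwise. The
boundary areas 32² and 96² are not assigned by the convention's strict
inequalities; both resolve to medium here (the closure of the open
interval) — any total rule would do, this one is the least surprising.
Comparing both side lengths instead of the area is a defensible alternative
reading; area was chosen and is what `classify_object_size` documents.

Summary statistics round half-up to their printed precision (2 dp for
frames/min, nearest 10 for the resolution percentage), so 1/30 min⁻¹
reports as 0.03 frames/min and 1.33/0.35 µm/px as 380 %.

## Detection

The detector interface is a registry of named plug-ins (`DetectorPlugin`),
so a trained model can replace the default without touching the pipeline.
The built-in baseline is intentionally classical: Gaussian smoothing
(σ = 2 px) → threshold at 0.2 of the frame's dynamic range → connected
components → watershed splitting (markers at local maxima) of components
wider than `max_box_side` → tight boxes, confidence = relative peak
intensity, IoU-based non-maximum suppression at 0.6. Side-length limits
(4–40 px by default) reject noise specks and large debris; this is a much
cruder debris filter than a learned appearance model and is documented as
such. Bright-on-dark polarity is assumed; `invert` handles dark cells.
The baseline resolves the simulator's blob images essentially perfectly at
moderate density, but merged blobs in very dense scenes are beyond it —
which is precisely why the plug-in seam exists.

## Tracking

**Affinity.** A candidate link between a tracklet tail and a detection is
scored by six features, each in [0, 1], combined as a convex weighted sum
(defaults: appearance 0.15/0.15, motion 0.30/0.20/0.10/0.10):

- appearance: normalised cross-correlation of the two patches (resampled to
  16 × 16, mapped from [−1, 1] to [0, 1]) and intensity-histogram
  intersection (16 bins). Flat (zero-variance) patches cannot be
  correlated: two equal flat patches score 1, flat-vs-structured scores the
  neutral 0.5.
- motion: `1 − min(dist/(gate_px·gap), 1)` on centroid distance; IoU of the
  boxes; area ratio min/max; directional consistency `(1 + cos θ)/2`
  between the recent velocity and the proposed step (0.5 when either is
  undefined).

Motion dominates the default weights because low-resolution cells are
nearly indistinguishable by appearance; when no images are provided the
motion weights are renormalised to sum to 1 and appearance is skipped
entirely.

**Gating.** `gate_px` (default 25 px per frame step, sized to the largest
plausible 30-min displacement) makes farther candidates infeasible outright
rather than merely low-scoring — this is what prevents a cell whose true
match was missed from grabbing a neighbour. A link must additionally reach
`affinity_floor` (default 0.1).

**Stage 1 — frame-to-frame linking.** For each adjacent frame pair, the
assignment problem on cost `1 − affinity` is solved exactly
(`scipy.optimize.linear_sum_assignment`); matches costlier than
`1 − affinity_floor` are severed. Unmatched detections seed new tracklets,
so every detection belongs to exactly one tracklet (conservation is a
tested invariant). Global assignment, not greedy matching, is what keeps
identities straight when displacements approach inter-cell distances.

**Stage 2 — multi-stage association.** Stages s = 1 … `max_gap_frames`
(default 3) merge tracklet ends to tracklet starts with temporal gap ≤ s
and spatial gate `gate_px · gap`, scoring pairs with the same affinity but
with the tail extrapolated by its recent velocity across the gap. Each
stage is one global assignment; accepted merges are chained and the gap is
filled with linearly interpolated boxes flagged `interpolated`
(confidence 0, preserved through MOT round trips). Progressively loosening
the gate resolves easy continuations before risky long-gap merges.

**Cleaving.** Before the final stage, any step longer than `cleave_factor`
(default 4) times the track's median real-step length is cut; fragments
(boundary interpolated entries stripped, < 3-entry tracks exempt) re-enter
the final association stage, which is what repairs identity switches.

**Completeness.** `filter_complete_tracks` keeps tracks spanning frames
1…N with no missing frame, interpolated entries counting as present — the
criterion used to decide which tracks are usable for wound-repair analysis.

Determinism: detections are processed in sorted order (frame, y, x), the
assignment solver is deterministic, and all simulator randomness flows from
one seed, so reruns are byte-identical.

## Leading-edge identification

Computed on frame 1 (eligibility is defined at the start of repair).
Detection centers are binned into horizontal rows (bin 10 px), smoothed
with a centered moving average (5 bins, truncated at the edges). The
plateau density is the median of smoothed counts over bins above the
profile midrange; the wound band is the contiguous run of bins below
`alpha × plateau` (alpha 0.25) containing the global minimum — with tied
minima (several all-zero runs, e.g. empty image margins) the longest,
deepest run wins. Because a moving average smears the density step by half
a window (~20–30 px), each band boundary is then refined outward across
*raw*-count sub-threshold bins, placing the reported edge at the bin
boundary adjacent to the outermost cell-bearing bin; this is what brings
localisation to within one bin of the true edge rows. If no bin falls
below threshold the wound is closed: a `WoundClosedError` signal, which the
pipeline and report surface rather than crash on. A fully confluent or
border-touching band reports the same signal. Horizontal wounds are
assumed (the scratch tool used in this assay wounds horizontally); a
transpose handles vertical ones.

A track is a leading-edge track if its frame-1 center lies within `margin`
(default 50 px) of either edge on the monolayer side; it is annotated with
its wound direction (+y for top-edge cells, −y for bottom-edge). Default
sampling is 20 tracks per experiment, uniform without replacement, seeded;
a shortfall returns all eligible tracks with a warning.

The bin height and smoothing window must resolve the cell spacing (a
5-bin/50 px window needs at least one cell row per window); at the assay's
>1000 cells/frame density this is comfortably met.

## Migration metrics

For centers c₁…c_T (px), pixel size s (µm/px), interval Δt (min):
Euclidean s‖c_T − c₁‖; accumulated s Σ‖c_{t+1} − c_t‖; velocity =
accumulated / elapsed hours — i.e. mean speed along the path, not the net
displacement rate (the usual chemotaxis-tool convention; the net-rate
variant is a one-line change on the returned fields); directionality =
Euclidean/accumulated (0 for a stationary track by convention); y-FMI =
s · (signed wound-ward net y displacement)/accumulated, the sign chosen so
repairing cells score positive on *both* edges, making conditions
comparable across edges; end-point angle = direction of c_T − c₁ in a
wound-ward frame where the wound direction maps to +90°, in [0, 360)°. A
zero-displacement track reports angle 0 with an explicit `degenerate` flag
rather than an error. Interpolated entries are part of the trajectory.
Invariants tested: accumulated ≥ Euclidean; |y-FMI| ≤ directionality;
translation invariance; rotation invariance of the scalar metrics.

## Group statistics

Two-sample Wilcoxon–Mann–Whitney, two-sided. Exact mode enumerates all
C(n+m, n) labelings of the pooled midranks (vectorised; used automatically
for n + m ≤ 20 — at the default 20-track samples a pairwise comparison is
n + m = 40 and uses the normal mode); normal mode is the tie-corrected
normal approximation with continuity correction (scipy). The two-sided
p-value is the permutation probability of a U at least as far from nm/2 as
observed. At n = m = 8 the exact test's achieved size at nominal 0.05 is
0.0415 (the permutation distribution is discrete), and exact and normal
p-values agree within 0.02. Pairwise p-values are reported raw — multiple
comparisons deliberately uncorrected, as is conventional for these
six-metric panels — with a Bonferroni option exposed.

## Evaluation

CLEAR-MOT: per frame, ground-truth and hypothesis boxes are matched
one-to-one maximising total IoU among pairs with IoU ≥ 0.5 (the common MOT
threshold), previous-frame pairs preserved while still valid (continuity
rule). MOTA = 1 − (FP + FN + IDSW)/n_gt; an identity switch is counted when
a ground-truth track changes its matched hypothesis identity.
`complete_track_recovery` is the fraction of ground-truth tracks matched to
a single hypothesis identity in every frame. `detection_complete_recovery`
is the tracker-centric variant used with corrupted detections: a
ground-truth track counts as recovered when all of its *surviving*
detections end up in one pure hypothesis track (interior misses bridged by
interpolation do not break recovery; fragmentation or identity mixing
does). The distinction matters because i.i.d. dropout at rate p removes the
frame-1 or final-frame detection of a track with probability 1 − (1−p)² —
at p = 0.1 about 19 % of tracks — and no tracker can re-create a detection
that never existed; recovery over the detectable span measures the
association algorithm rather than the dropout process. IDF1/HOTA are out
of scope.

## Simulator

The simulator emulates the study conditions, not monolayer mechanics: two
confluent monolayers on a jittered grid (rows anchored so the outermost row
of each monolayer sits on its wound boundary — the ground-truth leading
edge), a wound band between them, 22 frames at 30-min intervals, 1.33
µm/px, and > 1000 cells per frame at the default 1620 × 1176 geometry
(20 px boxes: the small-object regime). Cells within `edge_depth` (60 px)
of their boundary take wound-ward steps ~ Normal(step_mean, step_sd) plus
lateral Normal(0, 1); interior cells jitter isotropically. Condition
presets differ only in step_mean: 3 / 8 / 15 px per frame for delayed /
control / accelerated — i.e. roughly 8 / 21 / 40 µm/h, spanning inhibited
to drug-accelerated epithelial migration at this resolution. Cells neither
divide nor die (mitosis handling is a tracker non-goal), and boxes may
overlap — collisions deliberately stress association. Frames are rendered
as Gaussian blobs (σ = box side/4, per-cell intensity U(0.6, 1)) with
additive Gaussian noise and optional static debris in the wound band.
`corrupt_detections` drops each true box i.i.d. with `p_miss`, jitters
corners, and adds uniform false positives — the stress input for the
tracker. All randomness flows from the config seed.

What the simulator does *not* reproduce — phase-contrast texture, cell
shape change, contact inhibition, proliferation at the wound edge —
bounds what passing tests show: they validate the association, wound and
statistics machinery under a known ground truth, not detector performance
on real micrographs (that is what the detector plug-in seam is for).

## Test and acceptance problem sizes

Deliberate sizing, chosen so the full suite runs in well under a minute
while keeping each check meaningful: the exact-recovery and gap-closing
movies use 120 cells × 22 frames at 40 px spacing with ≤ 6 px steps
(spacing > 2× the largest step, so ground truth is unambiguous and MOTA
must be exactly 1); leading-edge localisation uses 20 seeded frames at
24 px spacing against true edges at rows 500/700; the condition-ordering
check uses 450-cell movies with a 650 px wound band — wider than the
maximal 21-frame accelerated travel (~315 px), so opposing migration
streams do not interpenetrate, which keeps the check about metric ordering
rather than about tracking through head-on stream collisions; the
Mann–Whitney calibration uses 2000 null replicates at n = m = 8. The
assignment solver is verified against exhaustive permutation enumeration up
to 6 × 6 (200 matrices).

## Known limitations

- The baseline detector under-segments very dense or touching cells; swap
  in a trained detector through the registry for real micrographs.
- Gap closing interpolates linearly; strongly curving cells bridged across
  ≥ 2 missing frames acquire slightly biased interpolated boxes.
- The wound must be a single horizontal band; multiple or oblique wounds
  are out of scope.
- Leading-edge eligibility is decided on frame 1 only; cells that reach the
  edge later are not promoted.
- MOT text formats carry no physical units; metadata travels in the
  sidecar, and consumers must keep them paired.
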