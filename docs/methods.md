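# Methods

## Problem setting

Given K ≥ 1 candidate segmentations of one subject — 3-D integer label
volumes on a common voxel grid, already co-registered, using the BraTS
label convention (1 necrotic/non-enhancing tumor, 2 edema, 4 enhancing
tumor; 3 unused) — produce one consensus segmentation. No intensity images
are used: fusion operates purely on label volumes. Composite regions nest:
enhancing tumor ET = {4} ⊆ tumor core TC = {1, 4} ⊆ whole tumor
WT = {1, 2, 4}.

## Class-wise fusion and recombination

Both methods decompose the multi-class problem into binary ones. In
`raw_labels` mode each label is binarized and fused independently; in
`regions` mode the nested composites WT, TC, ET are fused instead. The
per-class results are recombined by painting masks in a precedence order
in which later labels overwrite earlier ones; the default [2, 1, 4]
mirrors the anatomical nesting (edema outermost, enhancing tumor the most
specific claim). In region mode the decode paints WT as 2, then TC as 1,
then ET as 4, which reconstructs a label map from nested region masks
exactly.

The two modes trade off differently. Raw-label fusion is faithful to
"one vote per class" but has a structural failure mode: where candidates
disagree about *which* tumor subclass a voxel is (commonly necrosis vs the
enhancing rim around it), the subclasses split the vote, no label reaches
half, and the fused volume acquires background holes *inside* the tumor.
On the default phantom panel this accounts for nearly all whole-tumor
error of raw-mode fusion (measured: 110 of 119 missed WT voxels lay in
the ground-truth necrosis region). Region mode is immune because the
subclass confusion vanishes under the union; it is therefore what the
whole-tumor experiments in `segfuse.experiments` use. Both modes are
exposed and tested.

## Majority voting

A voxel is assigned a class when the summed weight of candidates voting
for it is at least half the total weight; plain MAV uses equal weights. A
tie at exactly half counts as agreement — with an even number of equally
weighted candidates, a 50% split keeps the voxel. The vectorized vote adds
a relative tolerance of 1e-12 to absorb float summation order; exact ties
occur in practice only with equal weights, where sums are exact.

## Iterative SIMPLE

Per class:

1. Initialize the consensus F as the *unweighted* majority of all K
   candidates.
2. Iterate: score each retained candidate against F with the Dice
   coefficient φᵢ; drop candidates with φᵢ < τ; re-vote the survivors
   with weights φᵢᵖ to obtain F′. Converged when F′ = F and the retained
   set is unchanged; hard cap at `max_iter` = 25 (cap events are visible
   in the trace as `converged = false`).

**Dropout threshold.** τ = max(0, mean(φ) − α·std(φ)), population std,
α default 1.0, computed **once** from the first iteration's full-panel
scores and then held fixed. The alternative — recomputing τ over the
shrinking survivor set each iteration — makes the cut-point an order
statistic of survivor noise: for any roughly evenly spread score vector,
min(φ) < mean(φ) − std(φ) whenever K > 2, so some candidate falls below
the threshold in every iteration and the ensemble attrits to one or two
survivors regardless of quality. Observed consequence on phantom panels:
the consensus drifts toward a correlated error mode (e.g. the subset of
raters that happened to dilate the boundary), the genuinely best candidate
is scored low against that drifted consensus and dropped, and the fusion
degenerates to a copy of two biased candidates. Fixing the stringency at
the full-panel distribution keeps the intended behavior — failed
candidates score far below the panel mean and are dropped after each
iteration — while the consensus remains an ensemble average.

Related choices:

- The top-scoring candidate is never dropped, so the consensus stays
  defined under pathological disagreement. (For α ≥ 0 this guard is
  provably redundant, since τ ≤ mean(φ) ≤ max(φ); it is kept as a
  defensive invariant.)
- If every retained φᵢ is 0 (mutually disjoint masks whose majority is
  empty), all weights φᵢᵖ vanish and a weighted vote would be undefined;
  the vote falls back to equal weights, the consensus stays empty, and
  the loop converges.
- An all-empty class converges at iteration 1 with every candidate
  retained at φ = 1, by the Dice convention below.
- Weight exponent p = 1 by default (raw Dice as weight); larger p
  sharpens the weighting toward the top candidates.

Both fusion methods are deterministic and RNG-free; candidate order never
affects the result.

## Dice coefficient

DSC(A, B) = 2|A∩B| / (|A|+|B|), in [0, 1]. Conventions:
DSC(∅, ∅) = 1 (perfect agreement that a class is absent) and
DSC(∅, non-empty) = 0. The first matters inside SIMPLE: a candidate that
correctly reports an absent class must not be scored 0 and dropped for it.
Scores are kept at full precision and rounded (4 decimals) only in CLI
output.

## NIfTI I/O

Files are read with nibabel; values are rounded to the nearest integer
(many tools store labels as float), with deviation > 1e-3 treated as a
corrupt file rather than a label map. 4-D volumes with trailing singleton
dimensions are squeezed. Label 3 is rejected, not remapped — silent
remapping would hide upstream errors — with an explicit `remap` escape
hatch (e.g. `3:1`) for datasets using older codings. Output is always
uint8 with the affine stamped from a reference header (by convention the
first candidate's), giving bit-stable round-trips. Candidates must share
the grid exactly; affines may differ elementwise by ≤ 1e-3 (resampling
writes harmless last-digit drift), beyond which strict mode errors and
lenient mode warns and uses the first candidate's affine. No resampling is
ever performed.

## Synthetic phantom and rater simulation

The ground truth is three concentric ellipsoids on a 64×64×32 grid:
edema (semi-axes 18/14/10 voxels) ⊃ core (10/8/6) ⊃ necrosis (5/4/3),
labeled edema-shell 2, core rim 4, necrotic interior 1 — reproducing the
nested anatomy of a contrast-enhancing glioma label map. The seed jitters
the center (±2 voxels) and scales the radii (±10%) so seeds give
geometrically distinct, always-valid phantoms.

Simulated raters degrade the ground truth with three error modes, each
driven by its own counter-derived RNG stream from the profile's single
seed (`default_rng([seed, stage])`), so candidates are reproducible
independently of one another:

- **Boundary noise** — per label, a random dilation or erosion with a
  spherical structuring element, radius uniform in 0..`boundary_noise`.
- **False negatives** — a fraction `fn_rate` of the rater's tumor voxels
  deleted uniformly at random.
- **False positives** — `fp_blob_count` spherical blobs of a random tumor
  label placed fully outside (not even touching) the true whole tumor,
  emulating the isolated outlier detections single algorithms produce.

The standard study panel (`study_profiles`) contains seven competent
raters cycling four quality tiers (boundary noise 0–2, false-negative
rate 1–8%, one or two small blobs; whole-tumor Dice roughly 0.92–0.995 on
the default phantom) plus three corrupted raters (85% of tumor deleted,
six large blobs; whole-tumor Dice ≈ 0.2). The tier spread is deliberate:
the method's use case is a panel of *different* algorithms of varying
accuracy, and a panel of identically parameterized raters would both be
unrealistic and produce pathologically correlated errors.

What the phantom does **not** emulate: MR intensities and
appearance-driven errors, anatomically realistic tumor shapes
(infiltrative margins, multifocality), spatially correlated rater errors
beyond whole-surface dilation/erosion, and inter-rater error correlation.
Passing the synthetic experiments therefore demonstrates the fusion
mechanics — outlier removal, quality weighting, dropout — not clinical
segmentation accuracy on real data.

## Experiments and expected behavior

`segfuse.experiments` packages two seeded studies (used by the examples,
the test suite and `scripts/acceptance.py`; whole-tumor quantities use
region-mode fusion):

- **Shared-false-positive removal** — ten minimal-noise candidates, four
  carrying an identical blob outside the tumor. 4/10 is below half, so
  both methods remove the blob entirely while whole-tumor Dice stays
  > 0.95. The base candidates carry only 1% random misses because the
  scenario isolates the correlated-false-positive mechanism; under heavy
  uncorrelated noise SIMPLE's dropout can leave the blob carriers at
  ≥ half the retained weight, at which point the tie-inclusive vote
  resurrects the blob — a real limitation of dropout-based fusion worth
  knowing about.
- **Fusion vs individuals** — 20 derived seeds of the 7-mild + 3-corrupted
  panel. Expected: SIMPLE's whole-tumor Dice ≥ the best individual in
  ≥ 80% of seeds (the occasional loss is a seed where four or more mild
  raters happened to erode the boundary, an error mode majority voting
  cannot fix; the observed win rate across seed choices is ~75–95%),
  ≥ the median candidate in all seeds, all three corrupted raters absent
  from the final whole-tumor retained set in ≥ 90% of seeds (observed:
  all), and convergence well before the 25-iteration cap (observed: ≤ 4
  iterations).

Problem sizes throughout (64×64×32 grids, 10-candidate panels, 20 seeds,
oracle checks on 8×8×4 and 6×6×2 grids) are chosen so every experiment is
exhaustively checkable and the full suite runs in seconds on one CPU while
still exercising the same code paths as full-resolution volumes.

## Known limitations

- Fusion assumes co-registered inputs; grid mismatches are errors, never
  resampled away.
- Soft/probabilistic candidates are out of scope; votes are binary.
- Raw-label mode can produce in-tumor background holes under subclass
  confusion (see above); prefer region mode when nested-region semantics
  are acceptable.
- SIMPLE's dropout protects against low-quality outliers, not against
  correlated errors shared by a weighted majority of retained candidates.
- The iteration cap (25) has never been reached in the packaged
  experiments; if reached, the trace records the non-converged state
  rather than raising.
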