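# Methods

## Problem and model

Clinical organ delineation is ambiguous: different observers contour the
same organ differently, and a conventional segmentation network trained on
all data learns an "average" contour that may satisfy nobody.  `dvaseg`
implements a data variation-aware alternative: a single U-Net encoder
shared by K decoder paths, where each decoder is trained on its own subset
of the training scans.  If the subsets align with distinct delineation
styles present in the data, each decoder specializes, and the network
proposes K plausible segmentation variants per scan instead of one
compromise.

The subsets are not given; they are found by optimizing the assignment of
training scans to K groups so as to maximize the validation cohort score

    score = (1/N) * sum_i  max_k  S_ik

where S_ik is the quality of variant k on validation scan i, and the
row-wise max models a clinician picking the preferred variant for each
scan.  S_ik is the mean of the volumetric Dice coefficient and the
surface Dice at tolerance tau.  A per-slice alternative (max over variants
taken slice-wise before averaging) is available behind a configuration
switch; the per-scan form is the default.

## Quality metrics

* Volumetric Dice: `2|A∩B| / (|A|+|B|)`.
* Surface Dice: surfaces are the centres of foreground voxels with at
  least one face-adjacent background (or out-of-grid) neighbour, in mm
  using the anisotropic voxel spacing; the score is the fraction of both
  surfaces' points within tau of the other surface.  Point-set surfaces
  (not interpolated meshes) keep the metric exactly checkable against an
  all-pairs brute-force oracle, which the test suite does on random masks.
* Conventions: two empty masks score `empty_pair_value` (default 1.0);
  empty vs nonempty scores 0 for both metrics.
* Default tolerance tau = 2.0 mm, configurable.  The emulated acquisition
  has 0.59 mm in-plane resolution and 3 mm slice thickness; 2 mm is a
  conventional organ-scale tolerance between those two.

## Synthetic cohorts

The generator emulates the *structure* of a clinical contouring dataset
without any clinical data: one reference mask per scan, with a hidden
scan-level "style" controlling how the reference was drawn.

* Organ: a randomized superellipsoid (semi-axes 8-10.5 mm in-plane,
  18-24 mm cranio-caudally, exponent 2-3, jittered centre) on a
  32 x 48 x 48 grid at (3.0, 0.59, 0.59) mm spacing.
* Style: the reference contour is offset outward/inward by
  `polar_offset_mm` in the outer thirds of the organ's slice range (the
  base and apex, where real observer variation is largest) and by
  `mid_offset_mm` (usually 0) in the middle third, with optional per-slice
  Gaussian boundary jitter.  Offsets are applied by thresholding the
  anisotropy-correct signed Euclidean distance transform in mm, not by
  voxel dilation.
* Image: the smoothed organ indicator plus Gaussian intensity noise.
* Everything is reproducible from (seed, parameters); the base organ
  depends only on the seed, so two styles with the same seed offset the
  same underlying shape.

What the generator does *not* emulate: MRI physics, catheters, seminal
vesicles, neighbouring organs, or any within-scan inconsistency of the
reference.  Passing the recovery benchmarks therefore shows that the
machinery (metrics, routing, search) behaves as designed under planted,
well-separated variation — not that the method resolves the subtler
variation of clinical data.

## Network and training

A deliberately compact 2D U-Net operates on transversal slices
(implemented directly on NumPy arrays with im2col convolutions,
hand-derived backward passes and Adam; everything is float32 and seeded,
so training is bit-reproducible on one machine):

* Encoder (shared): three 3x3 conv + ReLU levels of widths W, 2W, 4W with
  2x2 max-pooling between levels (default W = 8).
* Decoder (per variant): two upsample + skip-concat + 3x3 conv levels and
  a 1x1 output convolution with sigmoid; all K decoders are
  architecturally identical with independent parameters.
* Loss: binary cross-entropy plus a soft-Dice term, per slice.
* Routing: mini-batches may mix subsets.  The encoder runs once per
  batch; each sample's loss flows back only through its subset's decoder,
  and the per-decoder feature gradients are scattered back for a single
  encoder backward pass.  Decoders with no samples in a batch receive no
  gradient and no optimizer-state update, so an untouched decoder stays
  bit-identical — the test suite asserts this.
* Slices within 3 slices of the organ's range are used for training
  (`slice_margin`); border-adjacent empty slices act as negatives, while
  far-field empty slices carry no signal and are skipped.  Prediction
  always covers the full volume, slice by slice, thresholded at 0.5.
* With K = 1 the model and training reduce exactly to the classical
  single-decoder baseline (same code path).

## Partition search

A seeded generational evolutionary algorithm over assignment vectors:
uniform initialization, tournament selection (configurable size,
default 2), per-gene relabeling mutation at rate 1/L by default (one
expected flip per child), elitism, and a repair operator that restores
`min_subset_size` (default 2) by moving genes out of the largest subset.  Evaluated groupings are cached
under a relabeling-invariant canonical key; only novel groupings consume
budget.  The optimizer is intentionally plain — the method is agnostic to
the search technique — and sits behind a single evaluate-partition
contract with three backends:

* `multi_decoder`: train one shared-encoder model per candidate partition
  at reduced "proxy" epochs and score its validation predictions;
* `one_net_per_subset`: one independent single-decoder model per subset;
* `oracle` (synthetic only): no training; S_ik is the fraction of subset
  k's scans sharing scan i's planted style.  A style-pure partition
  scores exactly 1, which makes tiny cohorts exhaustively verifiable.

## The recovery benchmark

The standard end-to-end exercise plants two styles (exactly +2 / -2 mm
polar offset, no boundary jitter, so the style partition is the exact
optimum of the landscape) in a 24-scan cohort (16 train / 6 val / 2 test)
and asks the full pipeline — search at 30 evaluations, then full
retraining on the best partition — to recover the styles.  Two design
requirements make recovery identifiable, and both are stated here because
getting them wrong silently voids the benchmark:

* The search-time surface tolerance must undercut the planted offset.
  At tau = 2.0 mm a systematic 2 mm boundary shift is inside tolerance,
  the surface term is constant across partitions, and the score carries
  no purity signal; the benchmark evaluates at tau = 1.0 mm.
* The validation split must express every planted style (the cohort is
  generated with at least 6 scans per style in training and 2 in
  validation).  With a single-style validation set, any partition with
  one subset biased toward that style maximizes the score and style
  recovery is unidentifiable in principle.

Proxy fidelity matters too: below roughly 20 epochs the evaluation
landscape is dominated by underfitting noise rather than subset purity.
The benchmark uses 20 proxy epochs with a width-6 encoder at learning
rate 5e-3 — the cheapest fidelity at which pure partitions separate
cleanly from mixed ones.  The search runs with population 4 and
tournament size 4 (fully elitist parent selection): within a budget of 30
evaluations, recovery needs on the order of twenty corrective single-gene
flips' worth of trials, so every child must descend from the incumbent
best rather than from tournament losers.  The benchmark reports the
adjusted Rand index between the
best partition and the planted styles, plus the two variants' mean
outer-third areas relative to the zero-offset base organ (a successful
run brackets 1.0: one variant contours wide, the other tight, at the
poles).

## Observer-study analytics

The study model: three observers grade four segmentation sources
(reference, classical baseline, and the two variants) per slice and per
scan on a 1-4 scale (reject / major correction / minor correction /
approve) and rank the sources per scan with ties.  Operations:

* Best-of-two merging (`dvas_best`): max of the two variants' grades, min
  of their ranks — the real-use situation where the clinician picks the
  preferred variant.  The packaged count table ships the published
  counts, whose variant columns are already merged; the record-level
  expansion used by count operations materialises both variant sources as
  identical copies of the merged values (a synthetic expansion — the
  record-level variant data were never published).
* Pearson chi-squared on 2 x G count tables (no continuity correction;
  zero-total columns dropped with df reduced), Bonferroni correction
  min(1, m p), and Cohen's kappa on variant-preference labels
  (variant1 / variant2 / tie) for each observer pair.
* Region analysis: the evaluated slice range splits into three contiguous
  groups (base / mid / apex) whose sizes differ by at most one, remainder
  to the earliest groups; per-region relative area is the variant's
  summed in-plane area divided by the reference's.

## Numerical and degenerate-input choices

* Nearest-surface queries use a k-d tree and agree bit-exactly with the
  brute-force oracle at test sizes.
* Chi-squared on identical rows returns statistic 0, p 1; a one-column
  table after zero-dropping returns df 0 and p 1.
* Cohen's kappa returns 1.0 when both sequences are identical and chance
  agreement is 1 (single shared label).
* Region split requires at least 3 slices.
* Masks must be strictly binary; soft masks are rejected at I/O.
* Cohort generation redraws the style assignment (derived reseed, bounded
  retries) until every split-level style requirement holds, and errors if
  the configuration makes it impossible.

## Problem sizes

Desk-scale defaults throughout: 32 x 48 x 48 voxel grids, cohorts of
12-24 scans, encoder widths 6-8, 20-30 training epochs, search budgets of
30 (training backend) to 500 (oracle backend) evaluations.  These sizes
were chosen so the whole pipeline, including the end-to-end benchmark,
runs in minutes on a single CPU core while preserving every structural
property of the method.

## Known limitations

* The NumPy network is single-threaded and desk-scale by design; it is
  not a clinical-resolution segmenter.
* Planted styles encode only polar size variation; shape or texture
  variation between observers is out of scope.
* The oracle backend presumes the planted style labels are the only
  source of quality differences, which is exactly true only for the
  synthetic generator.
* With very noisy proxy training or a homogeneous validation split the
  best-of-variants score cannot identify styles (see the benchmark
  requirements above); the package does not try to detect these
  conditions automatically.
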