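# Methods

## The problem

Contacts between protein secondary-structure elements (SSEs) — helix
pairs and parallel or anti-parallel strand pairs — leave distinctive
rectangular signatures in a predicted inter-residue contact map. The
rectangle spanned by two contacting SSEs' residue ranges contains a
characteristic line: parallel strands trace a diagonal (residue *i* of
one strand pairs with residue *j₀ + i* of the other), anti-parallel
strands an anti-diagonal, and packed helices a *dashed* anti-diagonal,
since only residues on the contacting helix faces touch. `ssedetect`
treats the contact map as an image and these rectangles as objects to
be detected, typed and localised; the selected detections are then used
downstream to re-weight residue-level contact losses and to evaluate
contact maps by the standard range-stratified top-*L/k* protocol.

## Detection model

The detector is a compact instance-detection stack in the Mask-RCNN
family, sized for a single CPU:

* **Feature pyramid.** A bottom-up path of stride-2, 3×3 convolutions
  (widths 8 → 16 → 32) feeds lateral 1×1 projections at strides 4, 8
  and 16; a top-down path upsamples coarser levels (nearest ×2) and
  sums them into the laterals, followed by a 3×3 smoothing convolution
  per level. Channel width is 32 throughout the pyramid. The map is
  symmetric, so only the upper triangle enters the network (the lower
  triangle is zeroed); maps are zero-padded to a multiple of the
  largest stride.
* **Region proposals.** A shared 3×3 convolution plus two 1×1 heads
  emit an objectness logit and four box deltas for each of 9 anchors
  per feature-map element — 3 scales {4, 8, 16} × 3 aspect ratios
  {1:2, 1:1, 2:1}, chosen to match the reported anchor count; the
  exact anchor table of the original work is not public. Every box is
  capped at 1/4 of the map area, reflecting how large a single
  SSE-pair rectangle can plausibly be. Proposals below an objectness
  floor (0.5) are dropped and at most 200 are kept.
* **ROI heads.** Each proposal is pooled to 14×14 by bilinear ROI
  alignment (one sample per bin at the bin centre, no quantisation)
  from the finest pyramid level, with the raw map added as an extra
  stride-1 channel. The pooled window covers the box plus a 25%
  context margin per side — the evidence for where a rectangle truly
  ends often lies just outside a proposal's edge, and without the
  margin the head would have to extrapolate it. The classification/box branch sees the pooled
  patch 2×2-average-pooled plus the raw channel at full resolution —
  the full-resolution channel is what lets the box branch localise
  pattern ends to sub-cell accuracy — through a 128-unit dense layer
  into 4 class logits (background, HH, EE_PAR, EE_ANTI) and 4
  class-agnostic box deltas. A small convolutional branch predicts a
  14×14 mask of contacting residue pairs for each positive ROI.
* **Inference.** The box head is applied four times, each pass
  re-pooling at the previous pass's refined box; the whole pass is
  repeated on the map's anti-diagonal reflection (which maps each
  contact class onto itself) and the reflected candidates are mapped
  back, cancelling any directional localisation bias of the heads;
  finally each candidate's rectangle is replaced by the score-weighted
  average of all same-class candidates agreeing with it at IoU ≥ 0.7
  before rounding to integer residue bounds. These steps only re-use
  the trained head; they exist because a correct detection here must
  exceed 0.8 IoU against rectangles as small as 4×4, i.e. sub-cell
  localisation.

Training minimises a weighted multi-task loss
`w_cls·L_cls + w_box·L_box + w_mask·L_mask` (cross-entropy, smooth-L1
on normalised deltas, per-cell binary cross-entropy), with
`w_cls = w_box = 1` and `w_mask = 0.1`. The mask weight must be the
smallest of the three — enforced as a configuration invariant —
because helix pairs produce dashed target masks that the mask head
systematically smooths into continuous lines; a small mask weight
keeps that error from dominating. Box-regression targets are divided
by per-coordinate scales (0.1, 0.1, 0.2, 0.2) so sub-cell errors still
carry gradient. Anchors are assigned positive at IoU ≥ 0.5 (plus the
best anchor per ground-truth box), negative below 0.3, ignored
between. Head ROIs mix current proposals, ground-truth boxes,
jittered ground truth (six coarse-to-fine jitters per box, with
proportionally more repeats for under-represented contact types) and
random negatives. Optimisation is Adam (initial rate 10⁻³, geometric
decay to 10⁻⁴ over 16 epochs), one map per step, gradients clipped at
global norm 10. All arithmetic is float64 numpy via the in-package
autodiff engine (`ssedetect.nn`), single-threaded and exactly
reproducible for a fixed seed.

## Candidate selection and scoring

Selection follows a greedy non-maximum scheme specific to this
problem: SSE-pair rectangles never overlap each other and never
straddle the diagonal. Candidates scoring below the confidence
threshold **T = 0.70** or overlapping the diagonal band (half-width 5
residues, aligned with the shortest evaluated sequence separation of
6) are discarded; the rest are sorted by descending score — ties
broken by larger area, then top-left corner, then type, making the
procedure a total order and hence input-order invariant — and
repeatedly the top rectangle is kept and everything sharing a cell
with it removed.

A selected rectangle is counted correct when its IoU with a
same-type ground-truth rectangle exceeds 0.8, matched greedily by
descending IoU with each side used at most once. IoU (rather than
one-sided coverage) is used because it penalises oversized boxes,
consistent with the shrink-style box calibration of the detection
head. Precision, recall and F-measure are reported per contact type
and overall.

## Matched-filter reference detector

`template_detect` is a non-learned reference used to validate the
pipeline independently of training. Binary templates of the three
patterns are slid over the upper triangle at sides 3–16 and scored by
normalised cross-correlation times a saturating signal-strength term
(mean intensity over the template's on-cells divided by 0.5, clipped
to 1). Correlation alone is scale-invariant and would let dim,
accidentally aligned background cells mimic a contact; the strength
term suppresses them. Each window hit is then *calibrated*: the
pattern line through the window is walked to its maximal run of cells
at or above the signal reference (0.5), tolerating dash-period gaps
for the helix pattern, and the run's bounding square is rescored in
place. Without calibration, a clean sub-window of a long line
outscores the full noisy window and selection fragments the pattern.
Scores are rounded to 6 decimals so floating-point noise cannot
defeat the larger-area tie-break.

## Synthetic data generator

The generator emulates, at desk scale, contact maps with planted
SSE-contact patterns so that training, selection and evaluation run
end-to-end with no external data. Defaults: maps of L = 96 residues,
5–8 segments (helices 5–12 residues, strands 4–9), 2–4 planted
contacts per map with type probabilities 0.4 : 0.2 : 0.4
(HH : EE_PAR : EE_ANTI), the composition of a mixed globular test
set. Foreground cells draw from a normal(0.8, 0.1) clipped to [0, 1];
background cells are independently non-zero with probability 0.05 and
uniform magnitude in [0, 0.4]; optional Gaussian blur is off by
default. The helix dash period is 4 (offsets 0, 1 modulo 4 along the
anti-diagonal are contacts). Contact count and types are drawn before
the placement-rejection loop so the type marginal stays exactly
multinomial; placement retries (up to 1000) only concern layout.
Every stochastic choice derives from the generator seed through spawned
generators — no global RNG state.

Four deliberate idealisations make the planted rectangle *exactly
identifiable* from the pattern, which the package's own exactness
checks (noise-free F = 1.0) require:

1. the two segments of a planted contact share one length, so the
   line spans the whole rectangle;
2. helix-contact lengths are drawn with length mod dash-period in
   {1, 2}, so the dashed line reaches the rectangle corner (a length-8
   helix pair's dashes stop 2 residues short, capping the achievable
   IoU at 0.56 — no detector could recover such a box);
3. contacting segments are separated by at least 7 residues, clearing
   the diagonal exclusion band;
4. no two planted lines share one (anti)diagonal with a gap of at most
   the dash period — two in-phase dashed helix lines two residues apart
   would merge into one perfect longer dashed pattern that no detector
   could split into its true rectangles.

Real maps honour none of these: strand pairs have unequal lengths and
partial registers, helix contact faces need not start at segment
boundaries, and co-evolution noise is structured, not independent.
Passing tests on this generator therefore demonstrates that the
machinery — feature extraction, proposal, typed localisation,
selection, scoring — is correct and trainable, not that the trained
weights transfer to real proteins.

## Ground-truth annotation

For real structures, SSEs are maximal runs of H or E in a 3-state
string (DSSP 8-state input is reduced H/G/I → H, E/B → E, else → C),
with minimum lengths 4 (helix) and 3 (strand). A same-kind segment
pair is in contact when at least 2 residue pairs have Cβ–Cβ distance
below 8 Å (Cα for glycine; residues without coordinates are infinitely
distant). Strand-pair orientation is the sign of the correlation
between row and column indices of the contacting cells; a degenerate
correlation ties to anti-parallel (the more common class) with a
warning. These cutoffs follow common practice; the conventions the
original work delegates to other tools are not restated there, so all
values are configuration-exposed.

## Downstream applications

Selected detections re-weight a residue-contact cross-entropy: every
pair inside a selected rectangle (score S_t) has its loss multiplied
by 1 + S_t, pairs outside by 1. Regions are disjoint by the selection
contract, so the multiplier is well defined; the weight matrix is
symmetric. The summation domain is upper-triangle pairs with sequence
separation ≥ 6, matching the evaluation bands (the loss would
otherwise be dominated by trivial neighbours); predictions are clamped
to [10⁻⁷, 1 − 10⁻⁷]. Contact-map evaluation uses the standard bands —
short [6, 11], medium [12, 23], long [24, ∞) — and reports the
fraction of true contacts among the top ⌊L/k⌋ pairs (k = 10, 5, 2, 1)
ranked by predicted probability, ties broken by coordinates.

## Numerical and design notes

* Asymmetric input matrices are symmetrised by averaging; values
  outside [0, 1] (raw coupling scores) are min–max rescaled, since
  downstream stages expect probabilities.
* Internal coordinates are 0-based half-open with selected regions in
  the upper triangle; on-disk detection files are 1-based inclusive.
* Feature-map sizes follow the padded map (a multiple of the largest
  stride), so levels nest exactly for the ×2 top-down path.
* Problem sizes in the test-suite and the acceptance script — 300
  training maps, 8 epochs, 50 held-out maps, 50 noise-free maps,
  1000-case oracle comparisons — are the package's chosen study
  conditions for a single-CPU run.
* Known limitations: square-only templates in the matched filter; no
  helix–strand or strand-turn contact types; the synthetic noise model
  has no spatial correlation; DSSP-based secondary structure requires
  an external DSSP executable and is skipped (returned as None) when
  absent.
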