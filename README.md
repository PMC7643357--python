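# ssedetect

Inference of contacts between protein secondary-structure elements
(SSEs) from predicted inter-residue contact maps.

Two SSEs in spatial contact leave a characteristic rectangular pattern
in the contact map: parallel β-strands trace a **diagonal line**,
anti-parallel β-strands an **anti-diagonal line**, and packed α-helices
a **dashed line** inside the rectangle spanned by their residue ranges.
`ssedetect` finds these rectangles with a small object-detection model
(feature pyramid → region proposals → ROI-aligned classification /
box-refinement / mask heads), keeps a non-overlapping high-confidence
subset with a greedy selection rule, and applies the result downstream:

* **typed inter-SSE contacts** — helix–helix (`HH`), parallel
  (`EE_PAR`) and anti-parallel (`EE_ANTI`) strand pairs, each with a
  rectangle, a confidence score *S_t* and an optional per-cell mask of
  contacting residues;
* **loss re-weighting** for residue-contact predictors — pairs inside
  a predicted contacting-SSE rectangle have their cross-entropy
  multiplied by 1 + *S_t*:
  `L_rw = Σ_{i<j} (1 + S_t(i,j)) · CE(i,j)`;
* **range-stratified evaluation** — top *L/10*, *L/5*, *L/2*, *L*
  accuracy for short [6, 11], medium [12, 23] and long [24, ∞)
  sequence separations.

Candidate rectangles are filtered at confidence threshold **T = 0.70**
and against a diagonal exclusion band, then selected greedily by score
so that no two kept rectangles share a cell; a selected rectangle is
correct when it overlaps a same-type native contact with IoU > 0.8.

A synthetic generator plants the three patterns into noisy maps with
full ground truth, so the entire pipeline — training included — runs on
one CPU with no external data. It is intended for method development
and testing; see `docs/methods.md` for the model, the generator's
idealisations, and what results on synthetic data do and do not show.

## Worked example

```sh
ssedetect simulate --n 3 --out demo --seed 7 --size 96
ssedetect detect --map demo/syn00000.mat --template --out demo/cand.tsv
ssedetect select --detections demo/cand.tsv --out demo/sel.tsv
ssedetect eval --pred demo/sel.tsv --truth demo/syn00000.truth.tsv
```

prints

```
wrote 3 samples to demo
2 candidates -> demo/cand.tsv
2 selected of 2 candidates -> demo/sel.tsv
type    tp  fp  fn  precision  recall  f_measure
HH      1   0   0   1.0        1.0     1.0
EE_PAR  1   0   0   1.0        1.0     1.0
EE_ANTI 0   0   0   0.0        0.0     0.0
overall 2   0   0   1.0        1.0     1.0
```

and `demo/sel.tsv` holds the two selected rectangles (1-based inclusive
coordinates on disk):

```
id        type    i_start  i_end  j_start  j_end  score
syn00000  EE_PAR  49       56     87       94     0.9709
syn00000  HH      8        16     73       81     0.9656
```

i.e. the first map contained a parallel strand pair (residues 49–56
against 87–94) and a helix pair (8–16 against 73–81), both recovered
exactly; this map had no anti-parallel pair, so that row is empty. The
`--template` flag uses the non-learned matched-filter detector; train
and apply the learned detector with

```sh
ssedetect simulate --n 300 --out train_data --seed 11
ssedetect train --data train_data --out model.npz --epochs 16 --seed 0
ssedetect detect --map demo/syn00000.mat --model model.npz --out demo/cand.tsv
```

and build the 1 + S_t weight matrix for a 96-residue protein with
`ssedetect reweight --detections demo/sel.tsv -L 96 --out weights.mat`.

The same pipeline runs on real inputs: CCMpred-style matrices or CASP
RR files for maps, FASTA-like or DSSP secondary structure, and PDB
coordinates for Cβ-distance ground-truth annotation
(`ssedetect.annotate_contacts`).

## Library layout

| module | contents |
| --- | --- |
| `ssedetect.io` | CCMpred matrices, CASP RR, detections TSV, secondary-structure parsing |
| `ssedetect.annotation` | SSE segmentation, Cβ-distance contact annotation, PDB reading |
| `ssedetect.synthetic` | planted-pattern contact-map generator |
| `ssedetect.detector` | feature pyramid, anchors, proposals, ROI heads, multi-task loss, training |
| `ssedetect.template` | matched-filter reference detector |
| `ssedetect.selection` / `ssedetect.evaluation` | greedy selection, diagonal filter, IoU matching, P/R/F reports |
| `ssedetect.application` | 1 + S_t weight maps, re-weighted cross-entropy, range bands, top-L/k |
| `ssedetect.nn` | the numpy autodiff engine behind the detector |
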