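# Methods

This note documents the models, conventions and numerical choices behind
`stampseq`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, what the simulator does and does not emulate, and where the
design was genuinely open.

## Units and geometry

All chip-side computation is in pixels; all biology-side statistics are in
micrometres. The single conversion constant is the chip pixel pitch,
**0.265 µm/px**, stored in `ChipMap` metadata and used everywhere (100 px
bins = 26.5 µm; the ~6.2 px cluster pitch = 1.64 µm). Bins are half-open
`[m·w, (m+1)·w)` anchored at the chip origin, in both axes, for every binning
step (the 30 px filter bins and the 100 px localization bins).

## Barcode processing

**Whitelist model.** The chip map is the whitelist: one 32-mer per cluster
with its coordinate. Barcodes observed at more than one distinct coordinate
(synthesis duplications, ~0.03% of clusters) are unusable and removed
entirely.

**Error correction.** Sequencing errors are modelled as substitutions only.
An off-whitelist barcode is corrected when it has a whitelist neighbour at
Hamming distance 1; among several neighbours the one with the highest read
support (summed UMI support observed in the counts table) wins, and an exact
tie is dropped rather than guessed, keeping correction deterministic. The
search hashes all 3·L single-substitution neighbours, so it is exact.

**Prevalent-barcode filter.** A barcode that detaches from the chip can be
swept into many droplets; it shows up as one 30 px bin with anomalously high
total UMI. Per iteration the filter computes per-bin totals, flags bins
exceeding *k* = 20 times the mean per-bin total over non-empty bins, and
removes, per flagged bin, the single cell with the highest UMI support in
that bin together with all of that cell's barcodes chip-wide; then it
re-evaluates, to convergence by default (`single_pass` exposes the one-shot
variant; which of the two the original procedure used is not determinable
from its description, so both exist). "Mean UMI" is read as the mean of
per-bin totals — the quantity the procedure sorts — with the per-barcode mean
available as a config switch. A bin exactly at the threshold is retained
(the rule is "exceeds"). Ties for the worst cell break to the
lexicographically smallest cell id.

## Localization

The classifier and assigner follow the core/secondary construction described
under "What it computes" in the README. Conventions that needed fixing:

- Core-center ties (two bins with equal max UMI) break to the smallest
  (col, row) index.
- The secondary 5×5 block may overlap the core block; each block is summed
  independently. Blocks at the chip border are truncated, not padded.
- With no bin outside the core the ratio is +∞ → unique.
- The candidate set for position assignment is the barcode coordinates inside
  the core (`candidates` widens it if desired). Cost ties break to the
  lexicographically smaller (x, y).
- Diffusion quantiles are UMI-weighted (each UMI is one observation) and by
  default computed over core barcodes only; a flag switches to all detected
  barcodes. d50 ≤ d75 ≤ d95 always.
- Cells with fewer than 2 spatial-barcode UMIs are unclassifiable and only
  counted in the summary.
- The optional tissue mask is an even-odd point-in-polygon test on assigned
  positions, boundary-inclusive.

**Multiplex recovery.** `demux_recovery` emulates running the experiment with
k ∈ {1, 2, 4, 8} multiplex barcodes by collapsing the 8 tubes into k
contiguous blocks and merging cells that share (block, droplet). Recovery
counts are non-decreasing in k because finer tube partitions only ever split
merged footprints; the strict gains come from co-droplet nuclei whose merged
footprint has multiple centers.

## Synthetic data

The generator emulates, with known truth: a jittered-grid chip (pitch 6.2 px,
Gaussian jitter at 15% of pitch, duplication rate 3×10⁻⁴); isotropic Gaussian
barcode diffusion — each UMI of a nucleus picks a cluster with probability
proportional to exp(−d²/2σ²), σ = 2 µm by default, so pooled capture offsets
follow a Rayleigh(σ) law; spatial-barcode depth NB(mean 50, dispersion 10)
floored at 20 UMIs per nucleus; uniform nucleus placement within labelled
niche regions (a CSR-compatible null); 8 multiplex tubes assigned uniformly
(so colliding nuclei land in distinct tubes with probability 7/8 for free);
droplet collisions by uniformly pairing a `co_droplet_rate` fraction of
nuclei; and debris as low-UMI (Poisson mean 3) barcode sets at uniform random
positions riding in a random nucleus's droplet — reproducing the
multiple-center failure mode the classifier must reject.

For district-level statistics, `simulate_cell_table` plants vertical strip
niches of 200 µm width (TLS-scale territories, deliberately wider than the
30 µm neighborhood radius so interiors dominate boundaries), each 70%
dominated by one cell type.

*Not emulated:* optics, amplification chemistry and indel errors; 3D tissue;
realistic transcriptome complexity (expression is NB with planted marker
folds); cell-type-dependent capture efficiency; segmentation noise in the
ground truth. Passing tests therefore demonstrate correctness of the
computation and calibration of the statistics under these idealized
conditions, not end-to-end performance on real sections.

With co-droplet collisions enabled, two nuclei can legitimately share a
cell id (same tube, same droplet); the truth table is keyed per nucleus, and
the one-cell-one-truth-row invariant holds exactly in the collision-free
setting used for accuracy evaluation.

## Spatial statistics

**Ro/e** uses the chi-square expected counts (outer product of margins over
the grand total); entries with zero expectation are reported as NaN rather
than inflated.

**PCCF** conditions on the observed point pattern: the null shuffles type
labels over fixed positions, which is the same operation as randomizing
positions among cells. "Within 30 µm" is inclusive; same-type pairs are
unordered with self-pairs excluded; the pair search (cKDTree) is
contract-tested against the all-pairs computation. When zero pairs are
observed the statistic is 0 by definition; a positive observation over an
all-zero null is flagged NaN. The two-sided p-value doubles the smaller
add-one tail.

**Districts.** Composition features live on the simplex; zero-neighbor cells
are excluded. The encoder is two mean-aggregation layers with self weight
(ReLU between, dropout 0.25 during training), trained full-batch with Adam
(lr 0.001, 150 epochs) on L = L_neighbor + λ·L_InfoNCE: a negative-sampling
proximity loss over sampled Delaunay edges (5 negatives per positive) plus an
in-batch InfoNCE term on cosine similarities at temperature τ = 0.3,
positives being graph neighbours. The loss pair is our concrete reading of
"the original unsupervised objective plus a contrastive component"; hidden/
output dims 64/32 are desk-scale defaults recorded in output metadata. All
randomness (init, sampling, dropout, Leiden) flows from one seed, and the
implementation is plain numpy with hand-derived gradients — small, inspectable
and exactly reproducible.

Leiden runs on a 15-NN graph of the embeddings. Two calibrations proved
necessary. First, duplicate-heavy embeddings (near-pure compositions) can
fragment the kNN graph into disconnected components that Leiden can never
merge; components are therefore bridged at their closest point pairs before
clustering, so the partition is governed by the resolution rather than by
accidental disconnection. Second, resolution 1.0 fragments district-scale
communities into ~16–18 pieces at these problem sizes; the default is 0.1,
which recovers planted 5-niche partitions (ARI ≈ 0.9) through both the
embedding path and the raw-feature baseline. The raw-feature Leiden baseline
is kept as a guard against embedding pathologies.

**Ligand–receptor screen.** The SCI is a bivariate spatial cross-product:
z-scored ligand expression in senders times z-scored receptor expression in
receivers, averaged over the binary within-100 µm weight matrix (an
unnormalized variant is available). Candidates require the ligand in ≥ 10
sender cells, or in ≥ 10% of senders with the receptor in ≥ 10% of receivers.
The null permutes positions within each role — with W fixed this is a
permutation of the expression vectors; when sender and receiver types
coincide one shared permutation is used. Testing is adaptive: sampling stops
once 30 null draws reach the observed SCI, reporting the sequential estimate
exceedances/draws (Besag & Clifford), which cannot cross the 0.005 screening
threshold and stays a valid p-value; otherwise the add-one estimator at the
full 1000 draws is used. "Normalized p" is taken to be the BH-adjusted value
(both raw and adjusted are emitted); significance is q < 0.005. A log fold
change with a non-positive ratio is reported as NaN — the logarithm is
undefined and inventing a sign would be worse. Zero-variance expression gives
SCI = 0 by convention, flagged; an empty weight matrix gives NaN.

**Migration.** Per clonotype, district mean pseudotimes orient one movement
per spanned district pair (all pairs, not only consecutive ones — df = 19
over 20 ordered categories for 5 districts forces the all-pairs reading);
exact ties contribute nothing, since the direction is indeterminate. The
chi-square test defaults to a uniform expected vector over the n(n−1) ordered
pairs with zeros included; a user-supplied expected vector is accepted. Route
banding measures each source-district cell's distance to the nearest cell of
the next district; band "0" is distance ≤ 1 µm (the discrete "at the
boundary" band needs a numeric rule), then half-open bands (0,50], (50,100],
(100,150] µm.

## Evaluation

The control-point transform is a full 6-dof least-squares affine
(`similarity=True` constrains to rotation + scale + shift via the Umeyama
closed form) — the appropriate family depends on how the imaging frame was
acquired, so both are exposed. Matching is globally-shortest-first greedy:
all candidate pairs ranked by distance, accepted when both endpoints are
free. This guarantees deterministic one-to-one pairings invariant to input
order; it is not the optimal assignment, but agrees with exhaustive
enumeration of the greedy rule and gives each truth nucleus at most one
partner. The random baseline samples uniform positions over the region and
matches them the same way. "Expressing a gene" means raw count > 0 for the
overlap-ratio concordance (|A∩B| / max(|A|,|B|), 0 when both empty).

## Problem sizes and determinism

Default test and acceptance problem sizes — 500-nucleus tissues on
1000×1000 px chips, 2000-cell district fixtures, 500 CSR replicates, 200
null interactions at ≤ 1000 permutations — were chosen so the full suite and
the acceptance script each complete in well under a minute on a laptop-class
core while leaving the statistical checks comfortably powered. Every stage is
deterministic under its seed; the pipeline writes its resolved configuration
next to its outputs.

## Known limitations

- The localization error on synthetic data (~0.8 µm median at σ = 2 µm,
  ~50 UMIs) is better than what mixed real tissue achieves; real sections add
  RNA quality, segmentation and chemistry noise the simulator does not model.
- The encoder is full-batch and dense; it is meant for 10³–10⁵ cells, not
  millions, and makes no claim of matching any particular GNN library's
  training dynamics.
- The prevalent-barcode filter's two ambiguity switches (iteration mode,
  mean definition) change which cells are removed on pathological inputs;
  defaults are documented above.
- Greedy matching can exceed the optimal-assignment total offset; offsets
  reported for accuracy evaluation are therefore slightly conservative.
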