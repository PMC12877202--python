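# stampseq

Processing and spatial statistics for **single-nucleus spatial barcoding**:
experiments in which a sequencing chip carries clusters of cleavable 32-mer
oligonucleotide barcodes at ~1.6 µm pitch, each barcode tied to a known (x, y)
chip coordinate. A tissue section laid on the chip releases barcodes into the
overlying nuclei; nuclei are then split across 8 multiplex tubes, droplet-
encapsulated and sequenced, so every nucleus ends up with a cloud of spatial
barcodes whose chip coordinates betray where it sat. This package turns those
barcode clouds back into positions and runs the downstream spatial analyses —
who lives where, who lives next to whom, who talks to whom, and who moved.

It is aimed at computational biologists processing chip-based spatial
barcoding runs, and at methods developers who want a fully simulatable
reference pipeline: every stage can be exercised on the built-in synthetic
chip/tissue generator with exact ground truth.

## What it computes

**Localization.** Per nucleus, barcode UMIs are summed on a 100 px (26.5 µm)
grid. The max-UMI bin plus its 24 neighbours form the *core*; the best bin
outside it anchors a *secondary* block. The core/secondary UMI ratio r
classifies the footprint (r ≥ 10 unique center, 10 > r ≥ 2 major, r < 2
multiple → discarded). Unique/major nuclei get the position

  x̂ = argmin_p Σ_b u_b · ‖p − x_b‖

over candidate barcode positions in the core — a discrete UMI-weighted
geometric median — with 50/75/95% diffusion quantiles as QC. Upstream,
chip barcodes at two coordinates are removed, observed barcodes are corrected
against the chip whitelist at Hamming distance 1 (highest read support wins),
and detached "prevalent" barcodes are filtered by 30 px-bin thresholding at
20× the mean bin UMI.

**Statistics on localized, typed cells.**

- *Ro/e*: observed / chi-square-expected counts per cluster × group; > 1
  means enrichment.
- *PCCF*: observed (a, b) pairs within 30 µm over the mean pair count across
  label permutations, with a two-sided permutation p-value.
- *Districts*: 30 µm neighborhood composition vectors → Delaunay graph → a
  small unsupervised GraphSAGE-style encoder (negative-sampling proximity
  loss + InfoNCE, τ = 0.3, λ = 0.3) → Leiden.
- *Ligand–receptor screen*: SCI = Σ w_ij l̃_i r̃_j / Σ w_ij over sender–receiver
  pairs within 100 µm, tested by adaptive within-type position permutation
  (≤ 1000 draws, Besag–Clifford early stopping), BH-corrected, with log₂ fold
  change over the null median.
- *Migration*: clonotypes shared between districts are oriented by mean
  pseudotime; counts over the n(n−1) ordered district pairs are tested
  against uniformity by chi-square (5 districts → 20 categories, df = 19),
  and IGHG1/IGHA1 isotype ratios are profiled per district and in distance
  bands (0, 0–50, 50–100, 100–150 µm) along a route.

## Worked example

Simulate a chip and tissue, run the pipeline, and inspect the reports:

```bash
stampseq run --outdir demo --seed 7
cat demo/localize_report.json demo/evaluate_report.json
```

```
{"unique": 518, "major": 0, "multiple": 0, "unclassifiable": 7,
 "off_tissue": 0, "localized": 518}
{"n_matched": 500, "mean_offset_um": 0.835, "median_offset_um": 0.805}
```

518 cells (500 simulated nuclei plus a few debris particles that form their
own tight low-UMI footprints) classify as unique-center; 7 barcode-poor cells
are unclassifiable. Matched one-to-one against the simulated ground-truth
centroids, localized nuclei sit a median of 0.81 µm from their true positions
— roughly σ/√n for the σ = 2 µm diffusion kernel at ~50 UMIs per nucleus —
versus ~7 µm for uniformly random positions on the same chip region.

The same stages are available from Python:

```python
from stampseq import synthdata, chip_io, localize

chip = synthdata.make_chip(synthdata.SyntheticChipSpec(seed=0))
counts, truth = synthdata.simulate_capture(
    chip, synthdata.SyntheticTissueSpec(n_nuclei=500, seed=0))
chip, _ = chip_io.dedup_chip_barcodes(chip)
positioned, _ = chip_io.attach_coordinates(counts, chip)
table, summary = localize.localize_all(positioned)
```

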