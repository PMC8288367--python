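# retinage

Region- and age-resolved analysis of primate retina single-cell atlases.

Primate retinal aging is regional and cell-type-specific: the cone-rich fovea
ages differently from the rod-rich periphery, a MYO9A⁻ rod subpopulation and
the H2 horizontal-cell subtype are depleted in aged human retina, and
ligand–receptor signalling between Müller glia, bipolar cells and rods shifts
with age. `retinage` packages the computational stages needed to quantify
these effects from gene × cell count matrices with donor, species, age and
region metadata:

- **annotate** — Leiden clustering in PCA space, marker-panel cell-type
  scoring, the MYO9A⁺/MYO9A⁻ rod split (transcript detection), the H1
  (LHX1⁺ PCP4⁺) vs H2 (ISL1⁺ CALB1⁺) horizontal-cell split (marker-score
  argmax), and proportion tables with percentile-bootstrap CIs.
- **trends** — monotone trend-gene screening across ordered age stages:
  gene called "up" iff stage means strictly increase and both adjacent
  Wilcoxon contrasts pass BH FDR ≤ α with |log₂FC| ≥ 0.25 (mirrored for
  "down").
- **aging** — per-cell pseudo-aging score
  `score = mean_w z(up genes) − mean_w z(down genes)`, min–max rescaled to
  [0, 1]; local-linear score-vs-age trajectories per region with bootstrap
  95% bands; a within-donor permutation test for the fovea–periphery
  gradient.
- **comm** — ligand–receptor differential networks: per cell type, gene
  magnitude = |log₂FC aged vs adult| z-scaled across genes; edge score =
  ligand-node + receptor-node magnitude; top-k filtering.
- **disease** — disease-gene set scores per cell type × region (gene-wise
  z-scaling across groups, mean over the set) with a size-matched
  random-gene-set bootstrap test, p = (1 + #{null ≥ obs}) / (B + 1).
- **xspecies** — one-to-one ortholog restriction and Spearman correlation of
  cell-type centroids, banded at 0.3 / 0.5.
- **simulate** — a negative-binomial generator that emulates the study
  structure (marker elevation, conserved per-gene baselines, regional and
  stage-dependent subtype mixtures, planted monotone trend genes and LR
  signals) with full ground truth, so every stage is testable by parameter
  recovery.

Inputs are 10x-style MTX/TSV triplets plus a `cells.tsv` metadata table
(`core.read_matrix` / `core.write_matrix`); marker panels and gene sets load
from YAML/TSV.

## Worked example

```bash
python examples/02_rod_and_hc_subtypes.py
```

```
human: MYO9A- rods 37.0% (configured 36.9%), foveal H1 91.8% (configured 92.0%)
  mid-stage H2 fraction 52.4% (configured 52.3%)
  aging-stage H2 fraction 14.4% (configured 14.2%)
macaque: MYO9A- rods 4.8% (configured 4.7%), foveal H1 60.0% (configured 60.0%)
  MYO9A- rods located peripherally: 98.6% (configured 98.6%)
```

The script simulates the study-conditions human atlas (16,686 rods with a
36.9% MYO9A⁻ mixture, five donors aged 35–87 spanning adult/mid/aging
stages) and the macaque atlas (36,904 rods, 4.7% MYO9A⁻, 98.6% of them
peripheral), then recovers each configured mixture through the subtype
classifiers — the recovered percentages differ from the configured ones only
by transcript-detection and counting noise. The other `examples/` scripts
walk through clustering + annotation, the trend screen (87 up / 121 down
planted genes recovered exactly), aging-score trajectories, the
communication network, and the disease/cross-species maps, each printing the
numbers it computes and a line on what they mean.

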