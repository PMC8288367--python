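# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions (tie-breaks, degenerate
inputs, tolerances) a maintainer needs.

## Data model and normalization

The universal input is a sparse gene × cell matrix of raw UMI counts with
per-cell metadata: donor, species ∈ {human, macaque}, age in years (real;
an 8-day infant encodes as ≈0.02), and region ∈ {fovea, periphery}. All
expression comparisons run on library-size-normalized, log-transformed
values `v(g,c) = ln(1 + count(g,c) · S / libsize(c))` with `S = 10⁴`
(counts-per-10k + log1p, the droplet convention). Cells with zero library
size are rejected with their barcodes listed. Depth rescaling of a cell
leaves its normalized values unchanged, and values are monotone in counts;
both properties are tested.

Fold changes are computed on de-logged (linear-scale) group means with a
pseudocount of 1: `log₂((m_a + 1)/(m_b + 1))`. The pseudocount bounds the
statistic for dropout-dominated genes; it also compresses fold changes of
genes whose normalized means are near or below 1, which is deliberate —
such genes carry little evidence. Differential expression uses the
two-sided Wilcoxon rank-sum test (tie-corrected normal approximation) with
Benjamini–Hochberg adjustment, and an expression filter requiring detection
in ≥ 10% of cells of at least one group. These are conventions, not
estimates of any particular upstream tool's behaviour.

## Donor stages

Donors are binned by age: adult 18–45, mid 46–70, aging 71–120 years (a
`StageMap` is an ordered list of non-overlapping closed intervals; ages
outside every interval are "unstaged" and excluded from staged analyses).
The human donor panel used throughout (35, 52, 63, 86, 87 y) lands one
donor in the adult bin and two in each later bin. Macaque donors (2–23 y)
largely fall outside the human-year bins; stage-dependent analyses are
human-only by design, matching where the stage structure is scientifically
meaningful.

## Synthetic-data generator

Counts are negative binomial with a log-link mean and shared dispersion
`r = 2`: `count(g,c) ~ NB(mean = exp(β₀(g) + Σ effects(g,c)) · d(c), r)`.

- `β₀(g)`: a conserved per-gene baseline, `ln(base_mean) + σ_g · z_g` with
  `σ_g = 0.5` and `z_g` drawn from a dedicated seed shared across datasets.
  Orthologous genes in real species pairs have correlated characteristic
  expression levels; without this term, cross-dataset centroid rank
  correlations degenerate to noise.
- `d(c)`: a per-cell lognormal depth factor (σ = 0.3) to exercise
  normalization.
- Cell-type markers add `marker_log_fold` (default 3) on the log-mean.
- Subtype-defining markers are set to an *absolute* level
  (`base_mean · e^fold`, overriding the gene's baseline draw): MYO9A at
  `e^4.8 · base_mean ≈ 60` counts in MYO9A⁺ rods (and a structural zero in
  MYO9A⁻ rods), the H1/H2 markers at `e^4 · base_mean ≈ 27`. This keeps
  detection-based classification error far below the recovery tolerances
  regardless of a gene's baseline draw; the real subtype markers are
  similarly decisive, which is precisely why they define the subtypes.
- Planted trend genes shift by ±`per_stage_log_fold` (default 1.0) per
  stage index in all cells of staged donors.
- Planted ligand–receptor signals shift the ligand in aged-stage cells of
  the sender type and the receptor in the receiver type.
- Optionally, planted up-trend genes take an extra log-fold in foveal cells
  (`fovea_up_gene_log_fold`) to create a regional aging gradient.

Subtype and regional placement counts are allocated deterministically
(largest-remainder rounding across donor × region blocks) rather than by
per-cell Bernoulli draws — a stratified assignment, so realized mixture
fractions equal configured ones up to integer rounding while all count
noise (and hence classifier behaviour) stays stochastic.

The horizontal-cell mixture is parameterized as the overall H2 fraction per
stage plus a fixed foveal H2 fraction; the peripheral fraction is derived.
For the human study conditions: foveal H2 = 8%, overall H2 = 44.4% (adult,
derived from the two regional fractions at the 30/70 foveal/peripheral HC
split), 52.3% (mid), 14.2% (aging). The human MYO9A⁻ placement matches the
rods' overall regional split (85% peripheral), reproducing the observed
similar MYO9A ratios in both human regions; the macaque placement is 98.6%
peripheral. Human rods number 16,686 and macaque rods 36,904, with other
cell types at a few thousand cells each — large enough that counting noise
sits well inside the recovery tolerances, small enough that the full
two-species pipeline simulates in under a minute.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the condition structure, spatial
structure, or cluster substructure within a cell type. Passing recovery
tests therefore demonstrates correctness of the estimators under the
declared model, not robustness to artefacts real droplet data may carry.

## Clustering and annotation

Clustering is Leiden community detection (resolution 1.0, two iterations,
seeded) on a 15-nearest-neighbour graph in 30-PC space, delegated to
scanpy. An all-identical-cells matrix has no principal axes and is rejected
as degenerate. Cluster labels come from the marker panel: per gene, cluster
means are z-scored across clusters; a cluster's score for a type is the
mean z over that type's markers; label = argmax with a lexicographic
tie-break recorded in a flag column (reproducibility over arbitrariness).
Cells inherit their cluster's label and score vector, mirroring a
cluster-then-annotate flow; subtype classifiers then act per cell:

- Rods: MYO9A⁺ iff ≥ 1 raw count (equivalently, normalized value > 0). The
  positivity threshold is the package's choice; expression-based ±
  assignments need *some* cutoff and detection is the least parametric one.
- Horizontal cells: H1 score = mean z(LHX1, PCP4), H2 score = mean
  z(ISL1, CALB1), z across the HC population; argmax, ties to H1
  (lexicographic, flagged).

Proportion tables bootstrap cells within each group (percentile interval,
default 1000 resamples); coverage is verified at ≈95% ± 3 pp on binomial
draws.

## Monotone trend screen

A gene is "up" across adult → mid → aging iff its stage means (linear
scale) strictly increase, both adjacent contrasts pass BH FDR ≤ 0.05
(Wilcoxon on cells pooled within stage), and both adjacent log₂FC ≥ 0.25;
"down" is the mirror. Requiring *both* adjacent steps to be individually
significant is the strictest reasonable reading of "continuously
increased/decreased" and is what makes the planted-recovery count exact:
signals confined to one step (e.g. aged-only ligand shifts) are excluded by
construction. A donor-level pseudobulk summary is provided for a stricter
screen. The per-cell-type fold-change table marks a cell type absent from a
stage as missing (NaN), never as zero.

## Aging score and trajectories

Score: weighted mean z-expression over up-genes minus over down-genes
(weights default 1; a weight hook accepts correlation-with-age weights),
min–max rescaled to [0, 1] over the dataset. The rescale is
order-preserving; extremal cells hit exactly 0 and 1. The packaged examples
use the generator's planted trend genes as the gene set; a TSV loader
(`gene`, `direction`, optional `weight`) accepts curated aging-gene
exports for real use.

Trajectories: local-linear (degree-1) kernel regression of score vs donor
age, Gaussian kernel, bandwidth = 0.5 × the age range, evaluated on a
25-point grid; 95% band from percentile bootstrap over cells stratified by
donor (default 200 resamples). With few distinct donor ages the smoother
reduces to a near-interpolation of age-group means, which is the honest
resolution of the design; the bandwidth choice matters little there. The
fovea-periphery gradient statistic is the mean fitted difference over the
grid; its p-value permutes region labels among cells within donor
(two-sided on |Δ|, `p = (1 + #exceed)/(n_perm + 1)`), which preserves the
donor-age structure under the null. Note the test is sensitive to *any*
source of regional score difference, including cell-type composition
differences between regions, not only regional shifts in the aging program
itself.

## Communication network

Per cell type, each gene's magnitude is |log₂FC| between aged and adult
cells of that type (a signed variant by flag), z-scaled across that type's
genes (all-zero profiles scale to zeros). An edge (ligand L, sender S) →
(receptor R, receiver T) exists when L is detected in ≥ 10% of S's cells
and R in ≥ 10% of T's; its score is the sum of the two node magnitudes.
`top_k` keeps the k highest-scoring edges (default 100) with a
deterministic tie-break (pair id, then sender, then receiver,
lexicographic). A small curated LR pair fixture ships for convenience
(VEGFA and its receptors included); any two-column TSV is accepted. No
per-pair permutation p-values are computed — the output is a ranked score
graph.

## Disease map

Each gene's mean expression per (cell type × region) group is z-scaled
across groups; a disease's score in a group is the mean over its present
genes (diseases with no present genes yield missing rows). The z-scale
makes scores comparable across gene sets of different sizes. The bootstrap
null resamples *genes* — size-matched random sets from expressed genes
(detection ≥ 5%) — rather than cells, because the question is gene-set
specificity given the expression landscape; `p = (1 + #{null ≥ obs})/(B+1)`
honours the 1/(B+1) floor and is seed-reproducible. Null draws are shared
across diseases of equal set size (identical in distribution, cheaper). BH
q-values across all (disease × group) rows accompany raw p. The packaged
55-disease/178-gene table builder is a synthetic shape fixture
(`make_synthetic_disease_table`); a loader accepts real disease–gene TSVs.

## Cross-species correlation

Both matrices are restricted to a user-supplied one-to-one ortholog table
(≥ 50 shared genes required), the second matrix's genes renamed onto the
first's symbols. Cell-type centroids are mean normalized expression
(types with < 3 cells rejected); correlation is Spearman by default
(robust to monotone transforms), Pearson by flag. Band labels: low below
0.3, mid for [0.3, 0.5] (closed interval — boundary values land in the
middle band), high above 0.5; the boundary behaviour is tested
exhaustively.
Joint-factorization approaches to cross-species integration are out of
scope; the ortholog mapping is user-supplied, never inferred from sequence.

## Problem sizes and tolerances

The study-scale configurations (≈31k human cells, ≈50k macaque cells,
2,000 genes) simulate and analyse in roughly half a minute each; unit tests
use a 1,200-cell six-type configuration with deeper libraries
(`base_mean = 2`) so that down-trending genes with unlucky low baseline
draws remain detectable at small cell counts — at study scale the power
comes from cell numbers instead. Calibration tests use 10 null simulations
(trend screen), 60 replicates (gradient-test uniformity, KS), 100 random
gene sets at B = 500 (bootstrap enrichment, KS), and 200 replicates
(bootstrap CI coverage). Numerical comparisons in tests use exact equality
where the arithmetic is exact (edge scores, round trips, rescale extremes)
and the recovery tolerances (±1–2 pp on percentages) where counting or
detection noise enters.

## Known limitations

- Marker scoring assumes clusters align with cell types; a cluster mixing
  two types gets a single label (the flag column only records score ties,
  not mixture).
- The trend screen's pooled-cell contrasts treat cells as exchangeable
  within stage; donor effects inside a stage inflate significance on real
  data (use the donor pseudobulk companion to check).
- The aging score is a linear signature; it does not model nonlinear gene
  trajectories, and its [0, 1] rescale is dataset-relative, so scores are
  not comparable across datasets.
- The gradient permutation test requires donors sampled in both regions.
- Bootstrap gene resampling ignores gene–gene correlation; on real data
  with co-regulated modules the null is mildly anti-conservative.
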