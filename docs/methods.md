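# Methods

## Data model

A study is a set of tissue slices ("samples"), each belonging to one of two
conditions (`control` / `mct8`). Per cell we carry micrometre coordinates,
sample and condition labels, and integer counts over a targeted gene panel.
All statistics treat the sample as the spatial unit: neighbor counts and
pairwise distances are never formed across samples, because different
slices share no coordinate frame.

## QC and normalization

Cells are retained when they have strictly more than `min_probes` (default
15) genes with at least one transcript and strictly more than
`min_transcripts` (default 20) transcripts. "Detected" means count ≥ 1
after probe collapsing; both thresholds are exposed for sensitivity
analysis. Normalization is library-size scaling over the full panel,
`log1p(count · scale / cell total)` with `scale = 10⁴` and natural log —
the dominant single-cell convention; the scale is configurable. Counts are
kept alongside the normalized layer, since the annotation rule operates on
raw counts.

## Marker-rule annotation

The panel maps each cell type to an exclusive marker set (defaults: NPC =
VIM/NOTCH1/BMP7, IPC = EOMES/BMP5, neuron = GATA3/DCN/SPOCK2/SOX4). A cell
is assigned type T iff it has ≥ `min_count` (default 1) raw counts for at
least one marker of T and zero detected markers of every other type; cells
hitting two types, or none, are `undefined`. We deliberately do not break
ties by majority — presence of a foreign marker is treated as evidence
against a clean identity. Overlapping panels are rejected at construction.

## Distance distributions and the KS comparison

For a type pair (A, B) we collect **all** pairwise Euclidean distances
between A-cells and B-cells within each sample (not nearest neighbors — a
nearest-neighbor variant would measure contact rather than overall spatial
organization, and the all-pairs set is what the pooled-ECDF comparison
needs), then pool samples per condition. The two conditions are compared by
the two-sample, two-sided Kolmogorov–Smirnov statistic with the asymptotic
p-value. Caveat, stated rather than "corrected": pairwise distances sharing
a cell are dependent, so the effective sample size is far below the pair
count and the p-value is descriptive. The D statistic itself is an honest
summary of the ECDF gap.

## Neighborhood metric and density classes

n(cell) = number of other cells of the same sample within `radius_um`
(default 100 μm, boundary **inclusive**: d ≤ r). All cells count as
neighbors regardless of annotation; a flag to restrict to annotated cells
is not provided because undefined cells still occupy space. Density classes:
sparse ⇔ n == 1, dense ⇔ n ≥ 5, everything else (including n == 0) is
`other` and excluded from sparse/dense contrasts. No edge correction is
applied; instead each cell's distance to its sample's coordinate bounding
box is emitted (`dist_to_border`) so users can filter rim cells.

## Density-effect regressions

Per cell type and gene, two arms, each BH-adjusted separately across genes:

- **Linear**: OLS of normalized expression on n over all cells of the type;
  slope, two-sided t-test p, and a 95% CI. Implemented as closed-form
  vectorized simple regression (slope = Sxy/Sxx, SE² = RSS/(m−2)/Sxx),
  verified against statsmodels per-gene fits in the test suite. Genes with
  zero variance are flagged and excluded from the BH family; a constant
  covariate skips the arm with a reason.
- **Logistic**: regression of density class (dense = 1, sparse = 0) on
  normalized expression over sparse ∪ dense cells of the type (statsmodels
  `Logit`, Wald p). The binary variable must be the outcome for a logistic
  model to be well-defined; this direction is a documented design choice.
  Complete separation or unstable standard errors are flagged records with
  non-estimable p, never a silent zero. The arm requires both classes
  present and ≥ 6 sparse+dense cells.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum test between conditions on the
normalized layer: exact null enumeration when the combined sample is ≤ 16
and tie-free, otherwise the normal approximation with tie and continuity
corrections. Effect size is avg log2FC = log2((mean expm1 x̄₁ + ε) /
(mean expm1 x̄₂ + ε)), ε = 10⁻⁹ — the back-transformed-mean convention the
0.26 threshold originates from. Genes with zero counts in both groups are
excluded *before* BH, so the family size m is the number of genes actually
tested (this changes q; they are reported as untested). Regimes: `cosmx`
(q < 0.05, no fold floor), `parse` (q < 0.05, |avg log2FC| ≥ 0.26),
`parse_strict` (q < 0.01, fold change > 1.5).

## Composition tests

Global Pearson χ² (no continuity correction; correction available as a
flag) on the cell-type × condition count table, expected counts from the
margins. Per-type decomposition: each type versus all others as a 2×2 table
against condition, χ² per type, BH across types. The 2×2 χ² without
correction is numerically identical to the two-proportion z-test, so the
choice between them is cosmetic. Expected counts below 5 attach a warning;
a zero margin is an error naming the empty row/column.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the imaging physics:

- **Geometry**: per sample, a homogeneous Poisson background of intensity
  β plus a Thomas cluster process (parents Poisson with intensity ρ,
  offspring count Poisson(μ) per parent, isotropic Gaussian displacement
  σ), clipped to the field. Chosen because the total intensity has the
  closed form β + ρμ, so moment checks can verify the simulator itself.
  Defaults: 3 mm × 3 mm field, β = 4×10⁻⁵ /μm², ρ = 4.5×10⁻⁶ /μm²,
  μ = 28, σ = 40 μm → ≈ 1,500 cells per control sample, in rosette-like
  aggregates; two samples per condition; the disease condition is thinned
  to 75% density (the condition-dependent density the analysis is meant to
  detect). Boundary clipping loses ~5% of offspring relative to β + ρμ.
- **Types**: drawn i.i.d. per cell from the condition's proportions
  (default 0.40 NPC / 0.20 IPC / 0.30 neuron / 0.10 undefined); an optional
  per-type multiplier shifts the disease condition's simplex.
- **Counts**: NB(mean, θ) per gene × cell with θ = 5 and baseline mean 0.5.
  Marker genes are **exclusive**: mean = baseline × fold (default fold 8)
  in the own type and 0 elsewhere. A multiplicative-off-type marker model
  was rejected: on a multi-gene panel it makes cross-type marker hits
  near-certain, which contradicts the mutually exclusive marker sets the
  annotation rule presumes. Planted condition effects multiply the disease
  condition's mean by 2^lfc; planted density effects multiply by
  exp(β·n), with n computed at generation time at the same 100 μm radius
  the analysis uses, so planted and estimated effects are commensurable.
  Independent Bernoulli dropout (default 2%) zeroes entries after the NB
  draw; ground truth is recorded before thinning.
- **Planted DE is balanced** (default 10 genes up, 10 down at |lfc| = 1).
  Unidirectional planted DE shifts per-cell library size, and library-size
  normalization then induces spurious condition shifts in every null gene —
  a real compositional artifact of this normalization, which the balanced
  default avoids so that null genes are genuinely null. Users who want to
  study the artifact can plant one-sided effects.
- **Determinism**: each (condition, sample) pair draws from an independent
  stream keyed by `SeedSequence([seed, condition_index, sample_index])`, so
  adding samples never perturbs earlier ones and equal seeds give
  byte-identical output files.

What the generator does **not** emulate: segmentation errors, transcript
spillover between adjacent cells, batch/slide effects, spatially coherent
type domains (types are i.i.d. given position), 3-D structure, or
probe-specific efficiency. Passing recovery tests therefore shows the
estimators are correct under the stated model, not that real organoid data
satisfy that model.

## Numerical choices and degenerate inputs

- Wilcoxon exact/asymptotic switch at combined n = 16 (exact and
  asymptotic p agree within 0.01 at 8 vs 8); fully tied samples get p = 1
  by convention, flagged.
- BH is statsmodels `fdr_bh`, verified against the literal quadratic-time
  step-up definition to 10⁻¹².
- KS uses the asymptotic p (pooled pair counts are far beyond exact-mode
  sizes); D = 0 implies p = 1.
- The density-gene exponent β·n is capped at 50 before exponentiation.
- Empty QC results are a warning-carrying outcome; the pipeline aborts at
  the annotation stage naming QC as the cause, so partial outputs up to
  that point remain inspectable.

## Problem sizes used by the test and acceptance runs

Recovery and calibration checks run at desk scale: ~300–600 cells per
condition and 200–530 genes, 25–100 replicate seeds per property, chosen so
each property is measured with Monte-Carlo error well inside its margin.
The default end-to-end study (~5,000 cells, 1,207 genes) runs once to
produce the summary quantities.

## Known limitations

- The KS p-value on pooled pairwise distances is anti-conservative (pair
  dependence); compare D values, not p-values, across studies.
- The logistic arm conditions on the sparse/dense dichotomy and discards
  `other` cells, which is statistically inefficient but mirrors the
  two-class contrast the analysis defines.
- Marker-rule annotation has no notion of doublets or ambient
  contamination; cells with foreign-marker contamination become
  `undefined` rather than being rescued.
- χ² composition tests treat cells as independent draws, ignoring
  within-sample correlation; with two samples per condition a
  mixed-model alternative is underpowered anyway, and this matches the
  analysis being reproduced.
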