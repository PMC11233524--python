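# Methods

`scmetgrade` compares the metabolic transcriptional state of two glioma
grades (high-grade, HG; low-grade, LG) at cell-type resolution from
single-cell UMI counts, and validates the findings in bulk cohorts with
clinical covariates and overall survival. This note records the statistical
model behind each stage, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## 1. Cell-type pathway activity

For one condition, let `E[g, j]` be the arithmetic mean of the normalized
expression of gene `g` over the cells of cell type `j`. Gene-level relative
expression is

    r[g, j] = E[g, j] / (1/K * sum_k E[g, k])

so that every defined gene has row mean exactly 1 across the K cell types;
genes whose mean is zero in all cell types are undefined and excluded. The
activity of pathway `t` in cell type `j` is the weighted mean

    A[t, j] = sum_{g in t} w_g * r[g, j] / sum_{g in t} w_g ,

with weights `w_g = 1 / (number of supplied pathways containing g)` so that
promiscuous genes contribute less. Activity 1 means "average metabolic
activity across cell types"; values above/below 1 mean the cell type is
enriched/depleted for that pathway's transcription relative to the other
cell types in the same condition.

**Normalization** is linear counts-per-10k (`scale = 1e4`, all-zero cells
left zero). The score is a ratio of means, so only library-size correction
is required; a log transform would distort mean ratios and is deliberately
not applied. The statistic is invariant to any global rescaling of the raw
counts.

**Outlier trimming.** Per cell type, genes with
`r[g, j] > Q3_j + 3*IQR_j` — quartiles taken over all defined genes in that
cell type — are excluded from pathway sums in that cell type
(`trim_iqr_factor = 3.0`, on by default). This guards real data against a
single explosively expressed gene dominating a small pathway. On
structure-free synthetic data the rule degenerates: when every gene's `r`
is 1 plus sampling noise, the gene-wide IQR collapses to that noise and any
genuinely shifted gene is clipped as an "outlier" (a planted fold-2 pathway
scores NaN). Recovery-style simulations therefore run with `trim=False`;
null-calibration simulations keep it on, where it behaves neutrally. Users
analysing real data should leave trimming on; the flag exists precisely so
this sensitivity can be examined.

**Permutation significance.** Cell-type labels are shuffled across cells
within the condition and the full score (group means, relative expression,
trimming, aggregation) is recomputed per permutation. The p-value is
two-sided around the neutral value 1 with a +1 correction:

    p[t, j] = (1 + #{ |A*[t, j] - 1| >= |A_obs[t, j] - 1| }) / (n_perm + 1)

so p is never 0 and lies in `[1/(n_perm+1), 1]`. Default `n_perm = 1000`.
Under exchangeable labels the test is calibrated: the measured rejection
rate at alpha = 0.05 with `n_perm = 999` is ~0.05 (the exact attainable
level is 49/1000 = 0.049 because p is discrete).

**Other defaults.** `min_cells = 10` per cell type per condition (smaller
groups give unstably estimated means and are dropped with a warning);
activities are computed per condition over pooled cells of all samples.

## 2. MCP calling

A (pathway, cell type) pair is a *lenient* metabolically changed pathway
(MCP) when its activities straddle neutrality: HG > 1 and LG < 1, or the
reverse. A *strict* MCP additionally requires the ratio HG/LG to exceed 1.1
or fall below 0.9. Both thresholds are configurable (`strict_hi`,
`strict_lo`). Activities exactly 1.0 fail the strict inequalities; pairs
missing in either condition are skipped; `a_lg = 0` with `a_hg > 1` yields
ratio +inf, satisfies the strict band, and is flagged rather than erroring
(small gene sets can legitimately produce zero means). An optional
significance gate (`p_gate`, default off) additionally requires both
conditions' permutation p-values below the gate.

Because activities are centred at 1 within each condition separately, a
fold planted entirely in one condition leaves the other condition's
activity centred exactly at 1, making the straddle condition a coin flip.
The recovery simulations therefore plant a fold-2 *condition contrast*
symmetrically (HG x sqrt(2), LG x 1/sqrt(2)), which is the signal shape the
rule is designed to detect; with that shape recovery is 20/20 seeds and the
null strict-call rate is ~0.

## 3. Differential expression

Single-cell: per gene, a two-sided Wilcoxon rank-sum on normalized
expression between the two conditions' cells of one cell type, with
`log2fc = log2((mean_A + 1) / (mean_B + 1))` on normalized means (HG over
LG). Bulk: per gene Welch t-test on log2 expression (`log2fc` = difference
of group means). The pass rule is strict on both sides: raw `p < 0.05` and
`|log2fc| > 0.58` (a 1.5-fold change); a gene at exactly 0.58 never passes.
BH-adjusted p-values are reported alongside but do not enter the pass rule.
Cross-validation intersects passing single-cell and bulk genes and keeps
only direction-concordant hits.

Numerical choices: scipy's exact Mann-Whitney distribution assumes no ties,
which UMI-derived data violate pervasively, so the exact method is used
only when both groups are small (< 30) *and* tie-free; otherwise the
tie-corrected normal approximation applies. Genes constant across both
groups get p = 1 and a `zero_variance` flag. The +1 pseudocount on
normalized means shrinks |log2fc| at low expression — users planting or
hunting borderline 1.5-fold changes should note the cut effectively demands
moderate expression.

Power is governed by the fold-change *point estimate*, not the rank test:
the sampling sd of log2fc at n cells/group is roughly
`sqrt(2 * (1/m + 1/size) / n) / ln 2` for NB mean m and size (inverse
overdispersion). At 200 cells/group the 0.678 - 0.58 margin of a 1.6-fold
gene is cleared in >= 95% of runs for size ~ 10 (BCV ~ 0.32, typical for
UMI data) but only ~60-80% under heavy overdispersion (size 2). The power
simulations use size 10 with well-expressed genes and this sensitivity is
the reason.

## 4. Bulk validation

**Sample-level pathway score.** A rank-based single-sample enrichment
statistic stands in for GSVA (the downstream stages accept any externally
computed samples x pathways table via TSV). Within a sample, genes are
ordered by expression (descending; ties broken by average rank then column
order, so the score is deterministic) and both the member and the
non-member running CDFs are weighted by `rank^alpha` (`alpha = 0.25`); the
score is the mean difference of the two weighted CDFs. Weighting *both*
sides — unlike the classical one-sided weighting — makes the null (random
gene sets under exchangeable expression) centred at zero by symmetry.
Scores are invariant to monotone per-sample transforms, positive when the
pathway's genes sit atop the sample's expression ranking, and missing (with
a warning) for pathways with no measured gene.

**Association tests.** Welch t-test for two-level clinical factors, one-way
ANOVA for more, per (pathway, factor), BH-adjusted within each factor
across the pathway panel. Levels with fewer than 2 samples are dropped with
a warning.

**Prognosis.** Per feature: (i) univariate Cox proportional hazards via
lifelines (Breslow tie handling), on the covariate standardized to unit SD
so hazard ratios are comparable across features; (ii) Kaplan-Meier with a
median split (ties at the median to the low group, so odd n favours the
low group) and a two-group log-rank test. Both p-values are reported — the
underlying study's notion of "significant for survival" could be either —
and BH-adjusted across the feature panel. Two-cohort screens are
intersected at `logrank_p < 0.05` with direction-agreement flags.
Degenerate features (constant, too few events: >= 10 required) are skipped
with a warning, not errors for the whole screen.

## 5. Synthetic data

**Single cell.** Negative-binomial counts with a common dispersion
(`nb_dispersion = 2.0`, i.e. var = m + m^2/2) on a gene x cell-type mean
matrix: lognormal gene baselines (`mu = 0.75, sigma = 1.0`), optional
multiplicative cell-type structure (`cell_type_logsd = 0.5`; set to 0 for
an exchangeable-label null world), condition-specific fold shifts planted
on chosen (pathway, cell type, condition) triples, lognormal per-cell
library factors (sigma 0.25), and a mitochondrial block (13 "MT-" genes)
carrying an expected ~8% of each cell's counts with per-cell jitter —
inside the per-cell mitochondrial-fraction range reported for droplet
glioma data — so QC thresholds have signal to act on. The cell-type mean
structure is shared between conditions, so with no planted shifts the
conditions are exactly exchangeable. Defaults (10 cell types, 200 cells per
type per condition, 2000 genes) are a desk-scale rendition of a
several-thousand-cell droplet experiment. Not emulated: doublets, batch
effects, gene-gene correlation beyond pathway-planted shifts, gene-specific
dispersions. A green recovery test therefore establishes that the
*statistics* behave as contracted on data matching their assumptions — not
that any particular biological claim about real gliomas is reproduced.

**Bulk.** Gaussian log2 expression (baseline N(8, 2), residual sd 1) with
monotone per-grade-step shifts planted on chosen genes; exponential
survival with hazard `h0 * exp(sum_g beta_g * z_g)` over standardized
planted prognostic genes (`h0 = 1/365` per day); independent `U(0, tau)`
censoring with tau solved numerically (Brent) so the expected censoring
fraction matches `censor_rate = 0.3`. Exponential hazards are the simplest
model satisfying the proportional-hazards assumption of the Cox stage.
Clinical factors (histology, IDH, 1p/19q, PRS type) are drawn with
grade-dependent frequencies for realism of the table; only grade drives
expression.

All generators are fully reproducible from their config seed.

## 6. QC

Per cell: `n_umi` (column sum), `n_genes` (nonzero count), `mito_frac`
(counts on genes with the configured prefix, default `MT-`, over total; 0
for empty cells). Default thresholds `min_genes = 200`, `min_umi = 500`,
`max_mito_frac = 0.2`, `max_genes` unset — conventional droplet cut-offs,
chosen because the source analyses report only post-QC summary ranges, not
their cuts; all overridable. No algorithmic doublet detection (an optional
`max_genes` cap stands in). Filtering is idempotent and monotone in each
threshold; a run removing every cell errors with advice rather than
continuing empty.

## 7. Pipeline and determinism

One global seed is expanded via `numpy.random.SeedSequence.spawn` into
independent per-stage streams, so changing one stage's permutation count
does not perturb another stage's draws. All output tables are TSV with
fixed column order and 6-significant-digit floats; the manifest carries
parameters, seed, package version and SHA-256 checksums of every input and
output. Two runs from the same config and seed are byte-identical.

## Known limitations

- The per-cell-type activity is a relative statistic: it compares cell
  types within a condition, so a pathway uniformly up in *all* cell types
  of one condition is invisible to it (and to MCP calling).
- The sample-level enrichment score is a documented stand-in for GSVA, not
  a replication of its Gaussian-kernel CDF estimate; absolute score values
  are not comparable between the two methods, though downstream tests are
  rank-assisted and method-agnostic.
- The synthetic worlds are deliberately simple (common dispersion, no
  batch structure, exponential survival); contracts verified on them bound
  statistical behaviour, not biological fidelity.
- No multivariable or penalized survival modelling; prognostic screening
  is univariate by design.
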