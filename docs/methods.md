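# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic cohort does and does not emulate, and the known
limitations.

## Synthetic cohort generator

Counts are negative binomial, sampled as a gamma–Poisson mixture with
`Var = mu + alpha * mu^2` and a single dispersion `alpha` shared across
genes (default 0.1, a typical 10x value; sharing matches the simplified
dispersion model used by the pseudobulk test). The mean for gene *g* in
cell *c* factorizes as

    mu[g, c] = w[g | sample, type] * L_c

where `w` is a relative-expression vector normalized to sum to one and
`L_c` is a per-cell lognormal library size around the modality depth
(`depth_mean_nucleus = 2849` — the cohort's printed per-nucleus average —
and `depth_mean_cell = 4000`, placing the 10,000-UMI QC cap at ~2.5× the
typical cell library, the usual way such bands are chosen; `lib_size_sigma
= 0.3`). The weight vector combines:

- a lognormal baseline (sigma 1.0) shared across samples;
- per-(gene, sample) biological noise, `exp(N(0, 0.25))` — this is what
  gives pseudobulk replicates realistic overdispersion;
- cell-type markers: 10 genes per type multiplied by `2^2` inside their
  type. Marker, condition-DE and age-gene baselines are drawn from the
  upper part of the lognormal because they stand in for genes an analyst
  would actually select — top population-enriched markers and genes
  quantifiable in pseudobulk — not for the expression floor;
- condition effects: 50 genes at ±1 log2 unit in DCM samples (half up,
  half down);
- age effects: per-gene log-linear slopes in standardized sample age with
  sign alternating. The slope is `beta = sigma * r / sqrt(1 - r^2)` where
  `sigma` is the biological-noise sd on the log2 scale, so the sample-level
  Pearson correlation with age approaches the target `r` (0.8 by default;
  Poisson counting noise on pseudobulk means costs a further ~0.01);
- sex-restricted genes: small blocks expressed exclusively in one sex,
  mimicking sex-chromosome transcripts;
- a mitochondrial block (`MT-` prefix) pinned to the modality's expected
  mito share (5% cells, 1% nuclei).

Doublets are explicit summed barcodes: pairs of same-sample cells of
distinct types, `Binomial(n_cells, rate)` of them, grouped into a dedicated
cluster label per parent-type pair — cluster-shaped positives, because the
removal procedure flags clusters. Per-sample depth multipliers default to
off (library size varies per cell around the modality depth only); the
`sample_depth_sigma` knob plants them explicitly for normalization-recovery
studies.

Not emulated: ambient RNA, UMI collisions, gene–gene correlation beyond the
planted effects, continuous cell states, and batch effects other than
modality. Passing recovery tests on this generator therefore demonstrates
that each statistic detects what it claims under its own model assumptions,
not robustness to those artefacts.

## QC and doublet removal

QC bounds are strict inequalities exactly as stated (a 2,000-UMI cell is
removed). The doublet rule flags cluster *k* iff

    #{signatures with cluster-mean z >= tau} >= 2   AND
    median UMI in k / dataset median UMI >= rho

with `tau = 0.5` and `rho = 1.5`. The threshold applies to cluster-mean
z-scores, not per-cell values, because doublets present as clusters; `rho`
defaults to 1.5 because summed barcodes carry about twice the typical
library. Iterative removal re-runs log-normalization, scaling and scoring
on the surviving cells each round (the flags must reflect the current
dataset), stopping when nothing is flagged or at the iteration cap (three
rounds for nuclei, two for cells, per the procedure this follows). Both
directions of Scrublet-style concordance are reported — the fraction of our
flagged cells with external score > 0.2 and the fraction of retained cells
at or below it — since either denominator is defensible.

## Signatures

Scoring operates on the natural-log of depth-normalized counts + 1 (cells
scaled to the dataset median depth), standardized per gene with sample sd
(n−1); zero-variance genes become all-zero rows rather than NaN. The
default per-cell score is the mean of the member genes' z-values. A
`literal` variant that adds the dataset cell count to the per-cell sum
before dividing by the set size is retained behind a flag: the added term
is constant across cells, so the two variants differ by exactly
`n_cells / |G|` and induce identical rankings and cell-to-cell differences
— the constant changes no comparison, which is why `mean` is the default.

## Pseudobulk and differential expression

Size factors follow the median-of-ratios convention with the geometric-mean
reference restricted to genes positive in every sample, and the factor
taken as the plain median of ratios. Normalized counts are `values / sf`;
the log transform is `log2(x + 1)` of normalized counts, recorded as such
in output metadata — a shrinkage-based regularized log is deliberately not
reimplemented, since the downstream Pearson screen is rank-robust and the
ridge machinery would be out of proportion to its role.

The NB Wald test estimates per-gene dispersion by pooled within-group
method of moments, `alpha = max(1e-8, (s^2 - mu)/mu^2)`, i.e. no shrinkage
and no independent filtering beyond a fixed base-mean ≥ 1 filter for the BH
pass (genes below it keep their raw p with `p_adj = NaN`). The statistic is
the ln-scale contrast of group means (pseudocount 1) over the delta-method
standard error `sqrt(sum_g (mu_g + alpha mu_g^2) / (n_g (mu_g + pc)^2))`,
with a two-sided normal p. Unshrunk `log2fc = log2((mu2+1)/(mu1+1))`,
group2 over group1. All-zero genes report p = 1, log2fc = 0.

The Wilcoxon test uses average ranks, exact enumeration of all
`C(n1+n2, n1)` assignments when the smaller group has ≤ 8 observations
(two-sided p as the permutation probability of a rank sum at least as far
from its expectation as observed — well-defined under ties), and otherwise
the tie-corrected normal approximation with continuity correction; the two
branches agree to ~0.011 at the n = 8 boundary, the lattice worst case.
Its log2FC convention — `log2((mean(expm1 x_2)+1)/(mean(expm1 x_1)+1))` on
log-normalized input, group2 over group1 — is recorded in result metadata.

The intersection rule takes genes with raw p < 0.05 in both tests and
|log2FC| > 0.1 in both with matching sign, split into up/down lists. Note
the single-cell test treats cells as replicates and is therefore
anticonservative at the sample level; the pseudobulk test is the binding
constraint, which is why the intersection's false-call rate tracks the Wald
test's ~5%.

## Age associations

The screen computes per-gene Pearson r against age within one condition
stratum (donor and DCM never mix) with p from the t transform on n−2
degrees of freedom, unadjusted — the screen threshold is phrased on raw p;
a BH option exists. Signature membership uses strict cuts (r > 0.6,
p < 0.05). The signature score standardizes each member gene across samples
and averages; regression is ordinary least squares of score on age with a
two-tailed t-test on the slope. `top_n` reproduces the plotting variant
that regresses on the 10 genes most correlated with age.

## Composition

Proportions (not raw counts) within the parent population are tested per
cluster with Welch's unequal-variance two-tailed t-test and
Welch–Satterthwaite degrees of freedom; p-values are reported raw (a BH
option exists) since per-cluster stars are conventionally placed on raw p.
No compositional transform is applied.

## iLISI

Neighborhood weights are Gaussian, `w_j ∝ exp(-beta d_j^2)`, with `beta`
bisected until the weight entropy equals `ln(perplexity)` (tolerance 1e-5,
≤ 64 iterations; all-equal distances short-circuit to uniform weights).
Neighbor search is exact brute force; the cell itself is excluded.

The plug-in index `1 / sum_b p_b^2` cannot reach the upper endpoint *B* for
a finite neighborhood: under true mixing proportions `pi`,
`E[sum p_b^2] = sum pi_b^2 (1 - S) + S` with `S = sum_j w_j^2`, so a
perfectly mixed two-batch embedding tops out near `2 - 2S` (about 1.92 at
perplexity 30 over 90 neighbors). The default estimator therefore applies
the weighted generalization of Simpson's classical small-sample correction,
`(sum p_b^2 - S) / (1 - S)`, clipped to the valid range `[1/B, 1]`, which
makes the index attain its nominal endpoints (1 for complete separation —
exactly; ~1.95–1.97 for perfect mixing, the residual gap coming from the
clip at the boundary). `correction=False` reproduces the plug-in
construction and is used in tests whose expected values are computed by
hand.

## Over-representation

The hypergeometric upper tail `P(X >= k)` with population = universe,
successes = set ∩ universe, draws = query; the one-sided Fisher exact test
on the equivalent 2×2 table is provided as an alternative and agrees to
machine precision (the tests are the same tail). The universe defaults to
the genes tested in the originating DE analysis, per ORA convention;
query genes outside the universe are dropped with a warning. Enrichment is
one-sided (over-representation), the convention of the web tools this
replaces; BH runs across the collection.

## Numerical conventions and degenerate inputs

- Matrix Market files are 1-based per the standard; everything in memory is
  0-based; the boundary lives in the I/O module. Duplicate feature ids are
  disambiguated deterministically (".1", ".2", ...).
- Scaling a single-cell matrix (no sample sd) is an error, not a NaN.
- Empty doublet-flag sets make the flagged-side concordance NaN with a
  warning rather than raising.
- BH is the statsmodels step-up implementation; p-values outside [0, 1]
  are rejected.
- Zero-variance genes are excluded (flagged) from the age screen; genes
  absent from a matrix are dropped from signatures with a warning, and a
  fully absent signature is an error.

## Problem sizes

Tests and examples run the generator at the emulated cohort's design size
(38 samples, two modalities) with 100–200 cells per sample and 400–2,000
genes — enough for every planted effect to be comfortably detectable at its
stated rate while keeping the whole suite desk-scale. Monte-Carlo claims
(type-I error, recovery rates, false-flag rates) average 20 seeds.

## Known limitations

- The NB Wald test uses normal (not t) quantiles, as specified; at 10 vs 10
  samples its raw type-I error sits near 0.06 rather than 0.05 — the
  finite-sample inflation any unshrunk Wald test shows at that size.
- The single-cell Wilcoxon test treats cells as independent replicates;
  sample-level pseudoreplication makes it anticonservative on its own, and
  it should be interpreted only inside the intersection rule.
- Composition testing ignores the compositional (sum-to-one) constraint.
- iLISI assumes Euclidean geometry of the supplied embedding; it evaluates
  integrations but does not perform them.
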