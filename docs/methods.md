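# Methods

## The index

The matrisome index of a sample is a fixed linear form over a gene
signature, `score(s) = Σ_g β_g x_{g,s}`, computed on log2-scale
expression. The coefficients β_g are pretrained Cox log-hazard weights
and are treated as configuration: the shipped registry fixes the 29
gene symbols and their matrisome categories (3 collagens, 5 ECM
glycoproteins, 1 proteoglycan, 3 ECM regulators, 5 ECM-affiliated
proteins, 8 secreted factors, 4 other ECM-related genes), and a
coefficient file supplies the weights. The bundled
`data/example_coefficients.yaml` is a synthetic, illustrative set used
by the simulation pipeline and the documentation — it is not a
clinically trained model.

Signature genes absent from a matrix (removed by upstream filtering or
platform coverage) drop out of the sum; the number of genes actually
used is recorded per cohort. Scores from matrices with different gene
coverage are therefore on slightly different scales, which is why
stratification cutoffs are searched per cohort.

## Preprocessing

Count-scale inputs are filtered by the counts-per-million rule: keep a
gene if cpm ≥ 1 (boundary inclusive) in at least 20% of samples, with
cpm_j = 1e6·count/library-size(j). The same rule applies verbatim to
RPKM-like values. Both thresholds are parameters. Library normalization
(TMM) and precision weighting are assumed to have been applied upstream;
the package consumes normalized matrices.

Probe-level arrays are collapsed to genes by keeping, for each gene, the
probe with the highest mean expression across samples, copied verbatim;
ties break by input order. Per-sample maxima were rejected deliberately:
mixing values from different probes within one output row destroys probe
identity.

## Differential expression and the moderated t

Two-group comparisons at transcript and protein level share one
empirical-Bayes engine. Per-feature pooled variances s²_g (df d) are
shrunk toward a prior (d₀, s₀²) fitted by moment-matching on
log-variances (digamma/trigamma closed forms, trigamma inverted by
Newton iteration); the moderated t uses the posterior variance
(d₀s₀² + d s²)/(d₀+d) with d₀+d degrees of freedom, capped at the fully
pooled df. With d₀ = 0 the statistic reduces exactly to the ordinary
pooled t, a property the tests rely on. The implementation was verified
against R/Bioconductor limma on two fixtures (homoscedastic → infinite
prior df, heteroscedastic → finite prior df); the oracle statistics are
frozen in the test suite and agree to ~4e-15.

DEG ranks order genes by ascending BH-adjusted p, ties by descending
|log2FC|, then by symbol. The rank metric is a convention of this
package (several defensible choices exist); it is documented rather
than configurable.

## Generic signature weights

`weight(g) = Σ_d log2(fc_gd) · 2.0/(P_gd+1.0) · n_d / Σ_i n_i`, where
the denominator sums cohort sizes only over the diseases in which gene
g is present — every gene can have a different effective denominator.
P is the BH-adjusted p value. Selection uses a strict `> 3.90`
comparison. The engine is disease-count agnostic and
permutation-invariant over disease order.

## Cutoff search and stratification

Candidates are midpoints between consecutive distinct scores that leave
at least a minimum fraction (default 0.1) of samples in each stratum.
Each candidate split is scored with the one-df logrank statistic; the
candidate with the largest statistic (equivalently smallest p, but
immune to p underflow) is returned together with the full scan table.
The minimal p is descriptive only — it is optimized over candidates and
carries that flag in the result; no correction is applied. Ties at the
cutoff go to the low stratum.

## Diagnostics

The empirical ROC uses all distinct thresholds; AUC is the trapezoid
integral, which equals the Mann–Whitney concordant-pair fraction (the
test suite checks this against brute-force pair counting). Orientation
is fixed so AUC ≥ 0.5 ("tumor scores higher"), with flips recorded. The
best threshold maximizes Youden's J; ties resolve to the lower
threshold. Binormal smoothing fits a = (μ₁−μ₀)/σ₁ and b = σ₀/σ₁ from
class moments (not ML on the curve — deterministic and adequate for
illustration), giving sens = Φ(a + b·Φ⁻¹(1−spec)) and smoothed
AUC = Φ(a/√(1+b²)).

## Survival

Kaplan–Meier estimation and Cox fitting are delegated to lifelines
(Efron ties, Wald 95% intervals). A Breslow-tie Newton–Raphson fit is
provided as an alternative tie method. The logrank statistic is
computed directly from the observed-minus-expected decomposition so the
cutoff scan can evaluate hundreds of candidate splits cheaply; it is
cross-checked in tests against lifelines and against the Cox
partial-likelihood score test at β = 0, which coincides with it exactly
on tie-free data. Categorical covariates are one-hot encoded with the
alphabetically first level as reference; rows with missing covariates
are dropped with a count. These encodings are a declared convention.

## Associations

Spearman correlations use average ranks; p values come from the t
approximation, replaced by exhaustive permutation enumeration for
n ≤ 9. The mutational-load association filters to tumors with ≥ 1
somatic mutation and correlates the index with log10 counts, reporting
the number excluded. Profile correlations (fraction tables, checkpoint
panels) compute BH q within the profile — one heatmap panel is one
multiple-testing family; q is emitted alongside, never replacing, the
raw p. Zero-variance columns are reported as undefined rather than
dropped. Group comparisons: Mann–Whitney (exact for small tie-free
samples, otherwise normal approximation with tie correction),
Kruskal–Wallis, and one-tailed Welch t with a user-declared direction —
directions are figure-level choices, not inferable conventions.

Breast-cancer subtyping from receptor status: basal-like iff ER−, PR−
and HER2− (evaluated first); otherwise luminal iff ER+ and/or HER2−;
the remaining determinate case (ER−, HER2+) is HER2-positive; any
unknown status that the decision actually needs yields "unclassified"
(three-valued logic).

## Single-sample enrichment and IPRES calls

The per-sample enrichment statistic is a rank-based running-sum
contrast: genes are ordered by decreasing expression (ties by symbol,
for determinism); walking down that order, the in-set cumulative weight
(position weight = rank-from-bottom^0.25, so highly expressed genes
weigh most) is contrasted with the uniform out-of-set cumulative count,
and the mean difference over all positions is the score. The statistic
is rank-based, hence invariant under strictly monotone transforms of a
sample's values, and a set covering all genes scores 0. This is a
documented replacement for the published GSVA kernel: the downstream
analysis consumes only z-standardized scores and a fixed mean-z
threshold, which any monotone rank-based per-sample statistic
preserves; the exponent (default 0.25) is configurable.

Scores are z-standardized per set across samples (sample SD); a sample
is IPRES-enriched when its mean z over the IPRES collection strictly
exceeds 0.35. Zero-variance sets are excluded from the mean with a
warning rather than imputed at z = 0 — an uninformative set should not
dilute the call. z-scores default to per-input-matrix standardization;
cohort-wise grouping is the caller's choice of input.

The responder filter keeps genes with logFC > 2 and Mann–Whitney
p < 0.1 (both strict) from a responders-vs-non-responders DE table; the
canonical source list is not bundled, and the generator emits a
conforming table.

## Proteomics

Protein DE between strata runs the shared moderated-t engine on log2
ratios. Fold changes use the signed convention FC = 2^Δ (Δ ≥ 0) /
−2^(−Δ) (Δ < 0), an involution with |FC| ≥ 1, so the up rule FC > 1.5
and the down rule FC < −1.5 are symmetric; both are strict, combined
with p < 0.05. Targeted comparisons are one-tailed Welch t tests in
user-declared directions with no multiplicity adjustment (figure-level
reporting); the number of tests is logged. Engine settings are plain
defaults (no trend/robust options) and are declared in output metadata.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes —
structure, not marginal realism:

* log2 expression ~ Normal(per-gene baseline ~ N(7, 1.5), SD 1.0);
  tumors shift signature genes by ±effect_size with the sign of each
  gene's coefficient (default 2.0 log2 units, a four-fold change typical
  of strongly deregulated matrisome genes; a 1-log2 shift would cap the
  generic weight near 2, below the 3.90 selection threshold, making the
  default study degenerate for the weighting engine);
* additive per-cohort batch offsets ~ N(0, 0.3 log2 units), with a
  gene-specific mode available to stress probe collapse and scoring;
* survival: exponential event times with log-hazard γ per standard
  deviation of the realized index score (default γ = 0.5, HR ≈ 1.65 per
  SD; per-SD because the raw score scale depends on the user's
  coefficients), baseline hazard 1e-3/day, independent exponential
  censoring at 5e-4/day;
* mutational load: Gaussian copula on the score's normal scores with
  Pearson parameter 2·sin(π·ρ_S/6) for a Spearman target ρ_S (default
  0.4, inside the range reported for real cohorts), negative-binomial
  marginal (mean 30, size 1.0 → ~3% zeros, so the ≥ 1-mutation filter
  is exercised; the filter's truncation attenuates the realized
  post-filter Spearman to ≈ 0.38);
* immune fractions: logistic-normal over the 22 LM22 cell-type names
  with one component's location linear in the standardized score
  (default slope 1.0); rows sum to 1 exactly;
* proteome: tumor expression plus N(0, 2.4 log2 units) noise on a
  shared gene subset, centered per protein (pooled-reference
  convention); the closed-form attenuation 1/√(1+σ²_noise/σ²_gene)
  and its Spearman image (6/π)·arcsin(ρ/2) are recorded in the truth
  record;
* a 693-row responder DE table with exactly 161 rows passing the strict
  responder filter, including planted boundary rows (logFC exactly 2,
  p exactly 0.1) that must be excluded.

Default cohort sizes are 150 tumors + 50 normals in each of 2 cohorts —
a mid-sized observational study per cohort; the test suite scales n up
or down per check (e.g. 2000 tumors for copula recovery, 400+400 for
the null run, where the AUC's null standard error is ~0.02).

All draws come from a single seeded generator; identical seeds give
bit-identical bundles. What passing tests on these bundles do *not*
show: robustness to heavy-tailed expression, platform-specific
intensity distributions, informative censoring, dependent gene-gene
correlation structure, or deconvolution estimation error — the
fraction tables are treated as given.

## Numerical conventions

* TSV round-trips are bit-identical (repr-based writing, round-trip
  float parsing on read).
* Fraction rows must sum to 1 within 1e-6 and are renormalized exactly.
* Strict inequalities wherever a threshold is printed as strict
  (> 3.90, > 0.35, > 2 / < 0.1, > 1.5 / < −1.5, p < 0.05).
* The cutoff scan requires ≥ 20 samples and ≥ 1 event; Cox fits refuse
  constant covariates and fewer events than covariates; non-convergence
  after 100 Newton iterations is an error reporting the gradient norm.
* Exact small-sample paths: Spearman permutation p for n ≤ 9,
  Mann–Whitney exact for combined n ≤ 12 without ties.

## Known limitations

* No batch-effect removal; the generator emulates batch structure but
  matrices are consumed as already merged/normalized.
* No deconvolution: fraction tables are inputs.
* No time-varying covariates, proportionality diagnostics, competing
  risks, or Firth correction for separation in Cox models.
* No confidence bands or time-dependent variants for ROC curves.
* The enrichment statistic is a documented stand-in with the same
  invariances as the published kernel, not a reimplementation of it.
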