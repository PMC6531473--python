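# mxi — matrisome-index scoring and immune-association toolkit

`mxi` scores bulk expression cohorts with a fixed-coefficient matrisome
gene signature and relates the resulting per-patient index to diagnosis,
survival, mutational burden, immune-cell composition, immunotherapy
gene signatures and matched proteomes.

The tumor matrisome index (TMI) is a 29-gene expression classifier built
from core matrisome components (collagens, ECM glycoproteins, a
proteoglycan) and ECM-associated components (regulators, affiliated
proteins, secreted factors, other ECM-related genes). For a sample *s*
with log2 expression *x*:

```
TMI(s) = Σ_g  β_g · x_{g,s}
```

where the sum runs over the signature genes present in the matrix and
β_g are predefined Cox proportional-hazards coefficients. The package
ships the 29-gene registry with matrisome categories; the coefficients
are configuration (the pretrained clinical weights are not bundled — an
illustrative synthetic set is provided for the simulation pipeline).

Around this linear score the toolkit implements:

* **Cross-disease ("generic") signature weighting.** For gene *g* over
  diseases *d* = 1..D with log2 fold change fc, adjusted p value P and
  cohort size n:

  ```
  weight(g) = Σ_d log2(fc_gd) · 2.0/(P_gd + 1.0) · n_d / Σ_i n_i
  ```

  with the normalizing sum over the diseases in which *g* survived
  preprocessing; genes with weight > 3.90 (strict) form the generic
  signature.
* **Outcome-based cutoff search** (significance-scan over candidate
  cutpoints with a logrank statistic) and low/high stratification.
* **Diagnostics**: Mann–Whitney tumor/normal comparison, empirical ROC
  with trapezoid AUC, Youden-optimal threshold, and binormal smoothing.
* **Survival**: Kaplan–Meier curves, logrank tests, uni-/multivariable
  Cox models (Efron ties, Wald intervals).
* **Associations**: Spearman correlations of the index with log10
  mutational load (≥ 1-mutation filter), immune-cell fraction tables
  (e.g. 22 LM22 cell types from deconvolution output) and checkpoint-gene
  panels, with per-family Benjamini–Hochberg q values.
* **Single-sample enrichment**: a rank-based running-sum statistic,
  z-standardized per set; samples whose mean z over the IPRES (innate
  anti-PD-1 resistance) collection strictly exceeds 0.35 are called
  IPRES-enriched. A responder signature is derived from a
  responders-vs-non-responders DE table by logFC > 2 and p < 0.1.
* **Proteomics**: moderated-t differential protein expression between
  strata on iTRAQ-style log2-ratio matrices with the signed fold-change
  convention (up: FC > 1.5 and p < 0.05; down: FC < −1.5 and p < 0.05),
  targeted one-tailed comparisons, mRNA–protein correlation and
  cross-stratifier overlap sets.
* **A synthetic-cohort generator** that plants all of the above
  structure (signature shift, batch offsets, score-linked survival, a
  Gaussian-copula mutational load, a score-linked fraction component, a
  noisy matched proteome, and a responder DE table) so the entire
  pipeline is testable without any external download.

## Worked example

Everything is available both as a library (`import mxi`) and through the
`mxi` command. A complete synthetic analysis:

```sh
mxi simulate --seed 7 --out bundle
# wrote 2 cohort(s) of 150+50 samples to bundle

mxi score --matrix bundle/expression_cohort1.tsv \
          --signature src/mxi/data/example_coefficients.yaml \
          --out scores.tsv
# scored 200 samples with 29 genes

mxi roc --scores scores.tsv --labels bundle/labels.tsv \
        --smooth binormal --out roc.tsv
# AUC 1.0000, best threshold 5.8033, smoothed AUC 1.0000

mxi stratify --scores scores.tsv --clinical bundle/clinical.tsv \
             --endpoint OS --out strata.tsv
# optimized cutoff 9.3605 (p is optimization-biased, descriptive only)
# strata: {'low': 107, 'high': 93}

mxi survival --scores strata.tsv --clinical bundle/clinical.tsv \
             --endpoint OS --out cox.tsv
# high-vs-low HR 2.588 (n=150, events=104)

mxi associate --scores strata.tsv --with bundle/mutations.tsv \
              --kind tmb --out tmb.tsv
# -> log10_tmb  n=144  r_s=0.393  P_s=1.1e-06
```

Reading the output: the planted four-fold signature shift separates
tumors from normals perfectly (AUC 1.0); the outcome-optimized cutpoint
splits the 150 tumors into strata whose high group carries a 2.6-fold
hazard (the generator plants a log-HR of 0.5 per score SD); and the
index correlates with log10 mutational load at r_s ≈ 0.39 among the 144
tumors with at least one mutation (planted copula target 0.4).

## Layout

* `src/mxi/io_formats.py` — TSV/GCT matrices, GMT sets, clinical and
  fraction tables, probe collapsing, the signature registry
* `src/mxi/preprocessing.py` — cpm filter, log2 transform
* `src/mxi/signature_scoring.py` — index computation, differential
  expression, DEG ranks, generic-signature weights
* `src/mxi/stratification.py` — cutoff scan, stratification, ROC
* `src/mxi/survival.py` — KM, logrank, Cox
* `src/mxi/association.py` — Spearman engine, TMB, profiles, group
  tests, receptor subtyping
* `src/mxi/enrichment.py` — single-sample enrichment, IPRES calls,
  responder filter
* `src/mxi/proteomics.py` — protein DE, targeted tests, overlaps
* `src/mxi/simulate.py` — the synthetic-cohort generator
* `docs/methods.md` — models, conventions and limitations
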