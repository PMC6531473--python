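"""Synthetic multi-cohort generator with the dependence structure the
analysis assumes.

The generator plants, on top of a Gaussian log2-expression background:

* a tumor-vs-normal shift on the signature genes (sign matched to each
  gene's coefficient so that tumors score high),
* additive per-cohort batch offsets,
* exponential survival times whose log hazard is linear in the
  standardized index score, with independent exponential censoring,
* mutation counts tied to the score through a Gaussian copula with a
  negative-binomial marginal (zeros permitted, to exercise the >= 1
  filter); for a Spearman target rho_S the copula's Pearson parameter is
  rho_P = 2 sin(pi * rho_S / 6),
* an immune-cell fraction table (logistic-normal over the 22 LM22 cell
  types) with one component's location linear in the score,
* a matched proteome = expression + Gaussian noise on shared genes,
* a responders-vs-non-responders DE table with an exact planted number of
  rows passing the responder filter.

Every draw comes from one seeded generator; the planted parameters are
returned in a truth record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    SignatureDefinition,
    example_signature,
    write_clinical,
    write_expression_matrix,
)
from .association import MutationLoadTable
from .proteomics import ProteomeMatrix
from .signature_scoring import compute_index

LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated", "Monocytes",
    "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson parameter achieving a Spearman target."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic study.

    Defaults describe a mid-sized observational cohort: a few hundred
    tumors per cohort with matched normals, a one-log2-unit planted
    signature shift, moderate batch structure, an index-survival log-HR of
    0.5 per score SD, a TMB rank-correlation in the range reported for
    real cohorts, and a weakly coupled proteome.
    """

    n_tumor: int = 150
    n_normal: int = 50
    n_genes: int = 500
    n_cohorts: int = 2
    effect_size: float = 2.0           # log2 units per signature gene (4-fold)
    batch_sd: float = 0.3              # log2 units
    gene_sd: float = 1.0               # within-gene biological + technical SD
    baseline_hazard: float = 1e-3      # events/day at the mean score
    gamma: float = 0.5                 # log-HR per SD of the index score
    censoring_rate: float = 5e-4       # events/day of the censoring process
    tmb_rho: float = 0.4               # target Spearman(score, TMB)
    tmb_mean: float = 30.0             # negative-binomial marginal mean
    tmb_dispersion: float = 1.0        # NB size; small -> overdispersed, zeros occur
    n_cell_types: int = 22
    fraction_slope: float = 1.0        # score-linked component's location slope
    fraction_sd: float = 0.5
    linked_cell_type: str = "Macrophages M0"
    proteome_fraction: float = 0.6     # fraction of genes with matched protein
    proteome_noise_sd: float = 2.4     # log2 units of protein-level noise
    responder_n_rows: int = 693
    responder_n_pass: int = 161
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal, self.n_genes, self.n_cohorts) < 1:
            raise ValueError("counts must be positive")
        if not -1 < self.tmb_rho < 1:
            raise ValueError("tmb_rho must lie in (-1, 1)")
        if min(self.batch_sd, self.gene_sd, self.proteome_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.responder_n_pass > self.responder_n_rows:
            raise ValueError("more passing rows than rows")


@dataclass
class CohortBundle:
    """Everything simulate_cohort emits, in pipeline-ready containers."""

    expression: dict[str, ExpressionMatrix]   # cohort id -> matrix (tumor+normal)
    tumor_normal: pd.Series                   # sample -> 'tumor'/'normal'
    clinical: ClinicalTable                   # tumors only
    mutations: MutationLoadTable
    fractions: pd.DataFrame
    proteome: ProteomeMatrix
    responder_de: pd.DataFrame
    signature: SignatureDefinition
    truth: dict = field(default_factory=dict)


def truth_record(bundle: CohortBundle) -> dict:
    """The planted parameters, for recovery tests."""
    return dict(bundle.truth)


def simulate_cohort(
    spec: SyntheticCohortSpec, signature: SignatureDefinition | None = None
) -> CohortBundle:
    """Generate the full synthetic bundle for one study specification."""
    rng = np.random.default_rng(spec.seed)
    if signature is None:
        signature = example_signature()

    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]
    sig_genes = list(signature.genes)
    # signature genes replace the first len(sig) background names
    if len(sig_genes) > spec.n_genes:
        raise ValueError("n_genes smaller than the signature")
    gene_names[: len(sig_genes)] = sig_genes
    base_mean = rng.normal(7.0, 1.5, size=spec.n_genes)

    effect = pd.Series(0.0, index=pd.Index(gene_names))
    effect.loc[sig_genes] = spec.effect_size * np.sign(
        signature.coefficients.reindex(sig_genes).to_numpy()
    )

    expression: dict[str, ExpressionMatrix] = {}
    label_parts = []
    all_tumor_cols: list[str] = []
    for c in range(spec.n_cohorts):
        cohort = f"cohort{c + 1}"
        n = spec.n_tumor + spec.n_normal
        cols = [f"{cohort}_s{i:04d}" for i in range(n)]
        tumor_cols = cols[: spec.n_tumor]
        vals = rng.normal(0.0, spec.gene_sd, size=(spec.n_genes, n))
        vals += base_mean[:, None]
        vals[:, : spec.n_tumor] += effect.to_numpy()[:, None]
        vals += rng.normal(0.0, spec.batch_sd, size=(spec.n_genes, 1))
        df = pd.DataFrame(vals, index=pd.Index(gene_names, name="gene"), columns=cols)
        expression[cohort] = ExpressionMatrix(df, scale="log2", cohort_id=cohort)
        label_parts.append(
            pd.Series(
                ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal, index=cols
            )
        )
        all_tumor_cols.extend(tumor_cols)
    tumor_normal = pd.concat(label_parts)

    # the planted downstream couplings act on the actual index score
    scores = pd.concat(
        [compute_index(m, signature).scores for m in expression.values()]
    ).loc[all_tumor_cols]
    z_score = (scores - scores.mean()) / scores.std(ddof=0)
    n_tum = len(z_score)

    # survival: exponential with log-hazard gamma * z, independent censoring
    hazard = spec.baseline_hazard * np.exp(spec.gamma * z_score.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n_tum)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    clin = pd.DataFrame(index=scores.index.copy())
    clin["OS_time"] = time
    clin["OS_event"] = event
    clin["age"] = rng.normal(62, 10, size=n_tum).round(1)
    clin["gender"] = rng.choice(["female", "male"], size=n_tum)
    clin["race"] = rng.choice(["asian", "black", "white"], size=n_tum)
    clin["pT"] = rng.choice(["T1", "T2", "T3", "T4"], size=n_tum)
    clin["pN"] = rng.choice(["N0", "N1"], size=n_tum)
    clin["pM"] = rng.choice(["M0", "M1"], size=n_tum, p=[0.85, 0.15])
    clin["stage"] = rng.choice(["I", "II", "III", "IV"], size=n_tum)
    for rc in ("ER", "PR", "HER2"):
        clin[rc] = rng.choice(
            ["positive", "negative", "unknown"], size=n_tum, p=[0.55, 0.4, 0.05]
        )
    clinical = ClinicalTable(clin)

    # TMB through a Gaussian copula on the score's normal scores
    rho_p = spearman_to_pearson(spec.tmb_rho)
    ranks = scores.rank(method="average").to_numpy()
    u_score = (ranks - 0.5) / n_tum
    z_s = _norm_ppf(u_score)
    z_t = rho_p * z_s + np.sqrt(1 - rho_p**2) * rng.standard_normal(n_tum)
    u_t = _norm_cdf(z_t)
    counts = _nbinom_ppf(u_t, spec.tmb_dispersion, spec.tmb_mean)
    mutations = MutationLoadTable(
        pd.Series(counts.astype(int), index=scores.index.copy())
    )

    # fractions: logistic-normal, one component location linear in z
    cell_types = list(LM22_CELL_TYPES[: spec.n_cell_types])
    if spec.linked_cell_type not in cell_types:
        cell_types[0] = spec.linked_cell_type
    eta = rng.normal(0.0, spec.fraction_sd, size=(n_tum, len(cell_types)))
    linked_idx = cell_types.index(spec.linked_cell_type)
    eta[:, linked_idx] += spec.fraction_slope * z_score.to_numpy()
    ex = np.exp(eta - eta.max(axis=1, keepdims=True))
    fractions = pd.DataFrame(
        ex / ex.sum(axis=1, keepdims=True), index=scores.index.copy(), columns=cell_types
    )

    # proteome: expression + noise on a shared gene subset, tumors only
    n_shared = max(1, int(round(spec.proteome_fraction * spec.n_genes)))
    shared = list(sig_genes) + [
        g for g in gene_names if g not in set(sig_genes)
    ][: max(0, n_shared - len(sig_genes))]
    expr_all = pd.concat([m.values for m in expression.values()], axis=1)
    prot_vals = expr_all.loc[shared, all_tumor_cols] + rng.normal(
        0.0, spec.proteome_noise_sd, size=(len(shared), n_tum)
    )
    prot_vals = prot_vals - prot_vals.mean(axis=1).to_numpy()[:, None]  # vs pooled ref
    proteome = ProteomeMatrix(prot_vals)

    responder_de = _responder_de_table(
        rng, spec.responder_n_rows, spec.responder_n_pass
    )

    gene_var = spec.gene_sd**2
    atten = 1.0 / np.sqrt(1.0 + spec.proteome_noise_sd**2 / gene_var)
    truth = {
        "effect_size": spec.effect_size,
        "gamma": spec.gamma,
        "tmb_rho": spec.tmb_rho,
        "fraction_slope": spec.fraction_slope,
        "linked_cell_type": spec.linked_cell_type,
        "responder_n_pass": spec.responder_n_pass,
        "proteome_pearson": float(atten),
        "proteome_spearman": float(6.0 / np.pi * np.arcsin(atten / 2.0)),
        "seed": spec.seed,
    }
    return CohortBundle(
        expression=expression,
        tumor_normal=tumor_normal,
        clinical=clinical,
        mutations=mutations,
        fractions=fractions,
        proteome=proteome,
        responder_de=responder_de,
        signature=signature,
        truth=truth,
    )


def _responder_de_table(
    rng: np.random.Generator, n_rows: int, n_pass: int
) -> pd.DataFrame:
    """DE table with an exact number of rows passing logFC > 2 & p < 0.1.

    Failing rows include strict-boundary cases (logFC exactly 2, p exactly
    0.1) so the filter's strictness is exercised.
    """
    genes = [f"RG{i:04d}" for i in range(n_rows)]
    logfc = np.empty(n_rows)
    p = np.empty(n_rows)
    logfc[:n_pass] = 2.0 + rng.uniform(0.1, 3.0, size=n_pass)
    p[:n_pass] = rng.uniform(0.0, 0.0999, size=n_pass)
    n_fail = n_rows - n_pass
    if n_fail:
        mode = rng.integers(0, 3, size=n_fail)
        logfc_f = np.where(
            mode == 0,
            rng.uniform(-3.0, 1.9, size=n_fail),       # fails the FC rule
            np.where(mode == 1, 2.0, 2.0 + rng.uniform(0.1, 3.0, size=n_fail)),
        )
        p_f = np.where(
            mode == 2,
            np.where(rng.random(n_fail) < 0.5, 0.1, rng.uniform(0.11, 1.0, size=n_fail)),
            np.where(mode == 1, rng.uniform(0.0, 0.09, size=n_fail),
                     rng.uniform(0.0, 1.0, size=n_fail)),
        )
        logfc[n_pass:] = logfc_f
        p[n_pass:] = p_f
    perm = rng.permutation(n_rows)
    return pd.DataFrame(
        {"logFC": logfc[perm], "p": p[perm]},
        index=pd.Index([genes[i] for i in perm], name="gene"),
    )


def _norm_ppf(u: np.ndarray) -> np.ndarray:
    from scipy import stats

    return stats.norm.ppf(u)


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return stats.norm.cdf(z)


def _nbinom_ppf(u: np.ndarray, size: float, mean: float) -> np.ndarray:
    from scipy import stats

    p = size / (size + mean)
    return stats.nbinom.ppf(u, size, p)


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Emit the bundle in the pipeline's input formats plus truth.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cohort, matrix in bundle.expression.items():
        write_expression_matrix(matrix, out / f"expression_{cohort}.tsv")
    bundle.tumor_normal.rename("label").to_frame().rename_axis("sample").to_csv(
        out / "labels.tsv", sep="\t"
    )
    write_clinical(bundle.clinical, out / "clinical.tsv")
    bundle.mutations.counts.rename("mutation_count").to_frame().rename_axis(
        "sample"
    ).to_csv(out / "mutations.tsv", sep="\t")
    bundle.fractions.rename_axis("sample").to_csv(out / "fractions.tsv", sep="\t")
    bundle.proteome.values.rename_axis("protein").to_csv(
        out / "proteome.tsv", sep="\t"
    )
    bundle.responder_de.to_csv(out / "responder_de.tsv", sep="\t")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(bundle.truth, fh)
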