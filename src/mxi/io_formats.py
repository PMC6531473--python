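"""Readers, writers and core containers for the pipeline's tabular formats.

The pipeline moves between a small set of plain-text formats: gene x sample
expression matrices (TSV or GCT 1.2), GMT gene-set collections, per-sample
clinical tables with named survival endpoints, immune-cell fraction tables
(deconvolution output, e.g. LM22's 22 cell types), and a YAML signature
config holding per-gene Cox coefficients and matrisome categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ENDPOINTS = ("OS", "DSS", "DFS", "RFS", "MFS", "PFS")

CATEGORIES = (
    "collagens",
    "ECM glycoproteins",
    "proteoglycan",
    "ECM regulators",
    "ECM-affiliated",
    "secreted factors",
    "other ECM-related",
    "unannotated",
)

#: The 29-gene tumor matrisome index (TMI) signature: core matrisome
#: (collagens, glycoproteins, proteoglycan) plus ECM-associated components,
#: as annotated in MatrisomeDB. Coefficients are deliberately absent here —
#: they are predefined Cox log-hazard weights supplied by configuration.
DEFAULT_SIGNATURE_GENES: tuple[tuple[str, str], ...] = (
    ("COL11A1", "collagens"),
    ("COL10A1", "collagens"),
    ("COL6A6", "collagens"),
    ("SPP1", "ECM glycoproteins"),
    ("CTHRC1", "ECM glycoproteins"),
    ("TNNC1", "ECM glycoproteins"),
    ("ABI3BP", "ECM glycoproteins"),
    ("PCOLCE2", "ECM glycoproteins"),
    ("OGN", "proteoglycan"),
    ("MMP12", "ECM regulators"),
    ("MMP1", "ECM regulators"),
    ("ADAMTS5", "ECM regulators"),
    ("GREM1", "ECM-affiliated"),
    ("SFTPC", "ECM-affiliated"),
    ("SFTPA2", "ECM-affiliated"),
    ("SFTPD", "ECM-affiliated"),
    ("FCN3", "ECM-affiliated"),
    ("S100A2", "secreted factors"),
    ("CXCL13", "secreted factors"),
    ("WIF1", "secreted factors"),
    ("CHRDL1", "secreted factors"),
    ("CXCL2", "secreted factors"),
    ("IL6", "secreted factors"),
    ("HHIP", "secreted factors"),
    ("S100A12", "secreted factors"),
    ("LPL", "other ECM-related"),
    ("CPB2", "other ECM-related"),
    ("MAMDC2", "other ECM-related"),
    ("CD36", "other ECM-related"),
)


class FormatError(ValueError):
    """A file violated the expectations of its declared dialect."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a declared scale.

    ``values`` is a DataFrame indexed by gene symbol (or probe id before
    collapsing) with one column per sample. ``scale`` is ``"log2"`` or
    ``"linear"``.
    """

    values: pd.DataFrame
    scale: str = "log2"
    cohort_id: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SignatureDefinition:
    """A named gene signature with per-gene coefficients and categories.

    ``entries`` is indexed by gene symbol with columns ``coefficient``
    (float, unitless Cox log-hazard weight) and ``category``.
    """

    name: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("signature must contain at least one gene")
        if self.entries.index.has_duplicates:
            dups = self.entries.index[self.entries.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate signature genes: {dups}")
        coef = self.entries["coefficient"]
        if coef.isna().any() or not np.isfinite(coef.to_numpy(dtype=float)).all():
            bad = self.entries.index[~np.isfinite(coef.to_numpy(dtype=float))].tolist()
            raise ValueError(
                f"missing or non-finite coefficient for {bad}; every signature "
                "gene requires a finite coefficient — supply one in the config"
            )
        bad_cat = set(self.entries["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown category labels: {sorted(bad_cat)}")

    @property
    def genes(self) -> pd.Index:
        return self.entries.index

    @property
    def coefficients(self) -> pd.Series:
        return self.entries["coefficient"].astype(float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations and survival endpoint records.

    ``data`` is indexed by sample id. Survival endpoints are stored as
    paired columns ``<endpoint>_time`` (days) and ``<endpoint>_event``
    (0/1); any of OS, DSS, DFS, RFS, MFS, PFS may be present. Optional
    covariate columns: stage, pT, pN, pM, age, race, gender, ER, PR, HER2.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        for ep in self.endpoints:
            t = self.data[f"{ep}_time"].dropna()
            e = self.data[f"{ep}_event"].dropna()
            if (t < 0).any():
                raise FormatError(f"negative {ep} time")
            if not e.isin([0, 1]).all():
                raise FormatError(f"{ep}_event must be 0/1")

    @property
    def endpoints(self) -> list[str]:
        return [
            ep
            for ep in ENDPOINTS
            if f"{ep}_time" in self.data.columns and f"{ep}_event" in self.data.columns
        ]

    def endpoint(self, name: str) -> pd.DataFrame:
        """Return a (time, event) frame for one endpoint, complete cases only."""
        if name not in self.endpoints:
            raise KeyError(f"endpoint {name!r} not present; have {self.endpoints}")
        out = self.data[[f"{name}_time", f"{name}_event"]].dropna()
        out.columns = ["time", "event"]
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional role tag per set."""

    sets: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    scale: str = "log2",
    cohort_id: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample matrix from TSV or GCT 1.2.

    The first column holds gene/probe ids; remaining columns are samples.
    Row and column order are preserved. Non-numeric cells and duplicate
    sample ids are hard errors.
    """
    path = Path(path)
    if dialect == "tsv":
        skiprows = 0
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"not a GCT 1.2 file (header {version!r})")
        skiprows = 2
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    with open(path) as fh:
        for _ in range(skiprows):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = header[2:] if dialect == "gct" else header[1:]
    seen: set[str] = set()
    dups: list[str] = []
    for c in sample_cols:
        if c in seen:
            dups.append(c)
        seen.add(c)
    if dups:
        raise FormatError(f"duplicate sample ids in {path.name}: {sorted(set(dups))}")

    df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    if dialect == "gct":  # GCT 1.2 always carries a Description column
        df = df.drop(columns=df.columns[0])
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} "
            f"in {path.name}: {df.iat[i, j]!r}"
        )
    # re-read numerically with exact (round-trip) float parsing
    values = pd.read_csv(
        path, sep="\t", skiprows=skiprows, index_col=0,
        float_precision="round_trip",
    )
    if dialect == "gct":
        values = values.drop(columns=values.columns[0])
    return ExpressionMatrix(values.astype(float), scale=scale, cohort_id=cohort_id)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect; round-trips bit-identically via repr floats."""
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For each gene the probe with the highest mean expression across samples
    is retained verbatim; ties break by input order. Probes absent from
    ``probe_map`` are dropped (count logged).
    """
    if not probe_map:
        raise ValueError("empty probe map")
    probes = matrix.values.index
    mapped = probes[probes.isin(probe_map.keys())]
    n_unmapped = len(probes) - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix maps to a gene")
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)

    sub = matrix.values.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene")
    means = sub.mean(axis=1).to_numpy()
    # stable argsort on -mean keeps input order among ties; first hit per gene wins
    order = np.argsort(-means, kind="stable")
    seen: dict[str, int] = {}
    for pos in order:
        g = genes[pos]
        if g not in seen:
            seen[g] = pos
    keep = sorted(seen.values())
    out = sub.iloc[keep].copy()
    out.index = pd.Index([genes[i] for i in keep], name="gene")
    return ExpressionMatrix(out, scale=matrix.scale, cohort_id=matrix.cohort_id)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path, role: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, member symbols."""
    sets: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: GMT line needs name, "
                    f"description and >=1 member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            dup = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dup += 1
                    continue
                seen.add(g)
                members.append(g)
            if dup:
                logger.warning("set %s: %d duplicate members dropped", name, dup)
            sets[name] = members
            if role is not None:
                roles[name] = role
    if not sets:
        raise FormatError(f"no gene sets in {path}")
    return GeneSetCollection(sets, roles)


# ---------------------------------------------------------------------------
# signature registry


def default_registry() -> pd.DataFrame:
    """The 29-gene matrisome signature (gene, category), coefficient-less."""
    return pd.DataFrame(
        DEFAULT_SIGNATURE_GENES, columns=["gene", "category"]
    ).set_index("gene")


def load_signature_registry(config: str | Path | Mapping) -> SignatureDefinition:
    """Build a signature from a YAML config.

    Config layout::

        name: tmi
        genes:
          COL11A1: {coefficient: 0.31}          # category from the registry
          MYGENE:  {coefficient: -0.2, category: unannotated}

    Genes found in the built-in 29-gene registry inherit their matrisome
    category; others must declare one. Coefficients are mandatory: they are
    pretrained Cox model weights and the package never invents them.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict) or "genes" not in cfg:
        raise ValueError("signature config must be a mapping with a 'genes' key")
    registry = default_registry()
    rows = []
    genes_cfg = cfg["genes"]
    if len(set(genes_cfg)) != len(genes_cfg):
        raise ValueError("duplicate gene in signature config")
    for gene, entry in genes_cfg.items():
        entry = entry or {}
        if "coefficient" not in entry or entry["coefficient"] is None:
            raise ValueError(
                f"gene {gene!r} has no coefficient; supply the pretrained Cox "
                "weight in the config"
            )
        category = entry.get("category")
        if category is None:
            category = (
                registry.loc[gene, "category"] if gene in registry.index else "unannotated"
            )
        rows.append((gene, float(entry["coefficient"]), category))
    entries = pd.DataFrame(
        rows, columns=["gene", "coefficient", "category"]
    ).set_index("gene")
    return SignatureDefinition(name=cfg.get("name", "signature"), entries=entries)


def example_signature() -> SignatureDefinition:
    """The 29-gene registry with bundled synthetic example coefficients.

    The shipped coefficients are illustrative values for the synthetic
    pipeline, not the pretrained clinical weights.
    """
    ref = resources.files("mxi.data").joinpath("example_coefficients.yaml")
    with resources.as_file(ref) as path:
        return load_signature_registry(path)


# ---------------------------------------------------------------------------
# clinical and fraction tables


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a TSV clinical table (sample id in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t")


def read_fraction_table(path: str | Path, tol: float = 1e-6) -> pd.DataFrame:
    """Read a sample x cell-type fraction table (deconvolution output).

    Rows must be non-negative and sum to 1 within ``tol``; rows inside the
    tolerance are renormalized exactly, rows outside it are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return validate_fractions(df, tol=tol)


def validate_fractions(df: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    if (df.to_numpy() < 0).any():
        i, j = np.argwhere(df.to_numpy() < 0)[0]
        raise FormatError(
            f"negative fraction at sample {df.index[i]!r}, "
            f"cell type {df.columns[j]!r}"
        )
    sums = df.sum(axis=1)
    off = (sums - 1.0).abs() > tol
    if off.any():
        bad = df.index[off].tolist()
        raise FormatError(f"fraction rows do not sum to 1 within {tol}: {bad[:5]}")
    return df.div(sums, axis=0)
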