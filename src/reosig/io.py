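"""Typed containers for all omics inputs and their TSV/GMT readers and writers.

Every matrix is a pandas DataFrame wrapped in a thin dataclass that enforces
the container's invariants on construction (unique identifiers, finite
values, declared value alphabet). Gene symbols are the join key across all
data types; TSV is the canonical exchange format (first column = feature id,
header row = sample ids).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "SurvivalTable",
    "DiscreteOmicsMatrix",
    "MethylationMatrix",
    "PPINetwork",
    "GeneSetCollection",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_drug_response_tsv",
    "read_survival_tsv",
    "read_ppi_tsv",
    "write_ppi_tsv",
    "read_gmt",
    "write_gmt",
    "rpkm_noise_filter",
    "collapse_features_mean",
    "filter_methylation_sites",
]


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dup[:5]))}")


def _check_finite(df: pd.DataFrame, what: str, allow_missing: bool = False) -> None:
    arr = df.to_numpy(dtype=float, copy=False)
    bad = ~np.isfinite(arr)
    if allow_missing:
        bad &= ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value in {what} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    ``scale`` declares the units: ``"log2"`` (microarray-like log intensity)
    or ``"rpkm"`` (RNA-seq normalized counts). Sample annotations (group,
    batch, stage, ...) ride along as a samples x keys frame.
    """

    values: pd.DataFrame
    scale: str = "log2"
    sample_annotations: pd.DataFrame | None = None
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "rpkm"):
            raise ValueError(f"unknown expression scale {self.scale!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        _check_finite(self.values, "expression matrix", self.allow_missing)
        if self.sample_annotations is not None:
            missing = self.sample_annotations.index.difference(self.values.columns)
            if len(missing):
                raise ValueError(f"annotation for unknown sample(s): {list(missing[:5])}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"gene(s) not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale,
                                self.sample_annotations, self.allow_missing)


@dataclass
class DrugResponseTable:
    """Per-cell-line GI50 (concentration giving 50% growth inhibition).

    Higher GI50 = more drug resistant. ``subtype`` is the optional
    resistant/sensitive panel label.
    """

    gi50: pd.Series
    subtype: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.gi50.index, "cell line")
        vals = self.gi50.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("GI50 values must be finite and positive")
        if self.subtype is not None:
            bad = set(self.subtype.unique()) - {"resistant", "sensitive"}
            if bad:
                raise ValueError(f"unknown subtype label(s): {sorted(bad)}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.gi50.index)


@dataclass
class SurvivalTable:
    """Right-censored time-to-event data (months) with optional clinical covariates.

    ``event`` is 1 for death/progression, 0 for censoring. Optional columns:
    ``stage`` in {I,II,III,IV}, ``grade`` in {moderate, poor/undifferentiated},
    ``gender`` in {female, male}.
    """

    data: pd.DataFrame

    STAGES = ("I", "II", "III", "IV")
    GRADES = ("moderate", "poor/undifferentiated")
    GENDERS = ("female", "male")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing required column {col!r}")
        t = self.data["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("survival times must be finite and >= 0")
        ev = set(self.data["event"].unique())
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, got {sorted(ev)}")
        for col, allowed in (("stage", self.STAGES), ("grade", self.GRADES),
                             ("gender", self.GENDERS)):
            if col in self.data.columns:
                bad = set(self.data[col].dropna().unique()) - set(allowed)
                if bad:
                    raise ValueError(f"unknown {col} value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, sample_ids) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])


_CN_STATES = frozenset({-2, -1, 0, 1, 2})
_MUT_STATES = frozenset({0, 1})


@dataclass
class DiscreteOmicsMatrix:
    """Discrete per-feature alteration states.

    ``mode="cn"`` holds GISTIC-style copy-number calls in {-2,-1,0,1,2}
    (features may be genes or cytoband region labels such as "7p22.1");
    ``mode="mutation"`` holds binary somatic-mutation indicators.
    """

    states: pd.DataFrame
    mode: str = "cn"

    def __post_init__(self) -> None:
        if self.mode not in ("cn", "mutation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        _check_unique(self.states.index, "feature")
        _check_unique(self.states.columns, "sample")
        alphabet = _CN_STATES if self.mode == "cn" else _MUT_STATES
        observed = set(np.unique(self.states.to_numpy()))
        if not observed <= alphabet:
            raise ValueError(
                f"states {sorted(observed - alphabet)} outside {self.mode} alphabet")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)


@dataclass
class MethylationMatrix:
    """Promoter-averaged methylation beta values (fraction methylated, in [0,1])."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "gene")
        _check_unique(self.beta.columns, "sample")
        arr = self.beta.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("beta values must be finite (no NA after preprocessing)")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class PPINetwork:
    """Undirected simple protein-protein interaction graph over gene symbols."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop(s) in PPI network: {loops[:3]}")

    @classmethod
    def from_edges(cls, edges) -> "PPINetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_in(self, gene: str, target_set: set) -> set:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene)) & set(target_set)


@dataclass
class GeneSetCollection:
    """pathway_id -> (name, gene set) mapping, GMT-style."""

    sets: dict

    def __post_init__(self) -> None:
        for pid, (name, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers

_MATRIX_KINDS = ("expression", "cn", "mutation", "methylation")


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    try:
        out = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    return out


def read_matrix_tsv(path, kind: str, scale: str = "log2"):
    """Read a feature x sample TSV into the typed matrix for ``kind``.

    ``kind`` is one of expression / cn / mutation / methylation; ``scale``
    applies to expression matrices only.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"kind must be one of {_MATRIX_KINDS}, got {kind!r}")
    df = _read_numeric_tsv(path)
    if kind == "expression":
        return ExpressionMatrix(df, scale=scale)
    if kind == "methylation":
        return MethylationMatrix(df)
    return DiscreteOmicsMatrix(df.astype(int), mode=kind)


def write_matrix_tsv(matrix, path) -> None:
    df = getattr(matrix, "values", None)
    if df is None:
        df = getattr(matrix, "beta", None)
    if df is None:
        df = matrix.states
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_drug_response_tsv(path) -> DrugResponseTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    subtype = df["subtype"] if "subtype" in df.columns else None
    return DrugResponseTable(df["gi50"].astype(float), subtype)


def write_drug_response_tsv(table: DrugResponseTable, path) -> None:
    df = pd.DataFrame({"gi50": table.gi50})
    if table.subtype is not None:
        df["subtype"] = table.subtype
    df.to_csv(path, sep="\t", index_label="cell_line_id")


def read_survival_tsv(path, columns: Mapping[str, str] | None = None) -> SurvivalTable:
    """Read a survival TSV; ``columns`` maps canonical names (time, event,
    stage, grade, gender) to the file's column names when they differ."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return SurvivalTable(df)


def write_survival_tsv(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_ppi_tsv(path) -> PPINetwork:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    edges = [(a, b) for a, b in zip(df[0], df[1]) if a != b]
    return PPINetwork.from_edges(edges)


def write_ppi_tsv(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pid, name, genes = parts[0], parts[1], set(g for g in parts[2:] if g)
            if pid in sets:
                raise ValueError(f"duplicate pathway id {pid!r}")
            sets[pid] = (name, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, (name, genes) in collection.items():
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# matrix-level preprocessing


def rpkm_noise_filter(expr: ExpressionMatrix, threshold: float = 0.2,
                      frac: float = 0.75) -> ExpressionMatrix:
    """Drop genes at or below the RPKM noise floor in at least ``frac`` of samples.

    The boundary is inclusive on both counts: a gene with value == threshold
    in exactly ``frac`` of samples is removed. Gene order of survivors is
    preserved. Requires an RPKM-scale matrix.
    """
    if expr.scale != "rpkm":
        raise ValueError("noise filter applies to RPKM matrices, got scale "
                         f"{expr.scale!r}")
    low_frac = (expr.values <= threshold).mean(axis=1)
    keep = low_frac < frac - 1e-12
    return ExpressionMatrix(expr.values.loc[keep], "rpkm",
                            expr.sample_annotations, expr.allow_missing)


def collapse_features_mean(values: pd.DataFrame,
                           feature_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse multi-feature measurements to gene level by arithmetic mean.

    Used for both microarray probes and promoter CpG sites. Features absent
    from the mapping are dropped.
    """
    if not feature_to_gene:
        raise ValueError("empty feature-to-gene mapping")
    mapped = values.index.intersection(list(feature_to_gene))
    if len(mapped) == 0:
        raise ValueError("no feature in the matrix is covered by the mapping")
    sub = values.loc[mapped]
    genes = pd.Index([feature_to_gene[f] for f in mapped], name="gene_id")
    return sub.groupby(genes, sort=False).mean()


def filter_methylation_sites(beta: pd.DataFrame,
                             site_chromosome: Mapping[str, str] | None = None,
                             drop_masked: bool = True,
                             drop_sex_chromosomes: bool = True) -> pd.DataFrame:
    """Remove NA-masked CpG sites and sites on the X/Y chromosomes.

    ``site_chromosome`` maps site ids to chromosome labels; sites without an
    entry are kept (treated as autosomal) when sex-chromosome dropping is on.
    """
    out = beta
    if drop_masked:
        out = out.loc[~out.isna().any(axis=1)]
    if drop_sex_chromosomes and site_chromosome:
        sex = {f for f, c in site_chromosome.items()
               if str(c).lstrip("chr").upper() in ("X", "Y")}
        out = out.loc[~out.index.isin(sex)]
    return out
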