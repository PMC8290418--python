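"""Readers, writers and run configuration for every external format the pipeline touches.

Conventions shared across the package:

* Expression matrices are **genes × cells** in memory, always.  Readers
  transpose on the way in when a dense file stores cells in rows
  (``cells_in_rows=True``).
* Gene identity is the symbol string as given in the input; no alias
  resolution happens at load time.  Marker synonyms (e.g. CD25 vs IL2RA)
  are resolved explicitly by the gating step through a user-editable map.
* All output tables are TSV with a fixed column order; floats are
  serialised with 6 significant digits so outputs are diff-able.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("nsclc_scmet")

FLOAT_FMT = "%.6g"

LayerTag = str  # one of {"counts", "normalized", "lognorm"}
_VALID_LAYERS = ("counts", "normalized", "lognorm")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes × cells expression matrix with aligned per-cell metadata.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array of finite, non-negative values
        (counts or normalized units).
    gene_ids, cell_ids
        Unique identifier strings for rows and columns respectively.
    cell_meta
        Per-cell table aligned 1:1 with ``cell_ids`` (index = cell_ids);
        carries at least ``sample_id`` and optionally ``cluster_id`` /
        ``cell_type``.
    layer_tag
        Which unit the values are in: ``counts``, ``normalized`` (linear,
        depth-corrected) or ``lognorm`` (log1p of normalized).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame | None = None
    layer_tag: LayerTag = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × cells array")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng or len(self.cell_ids) != nc:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != ng:
            raise ValueError("duplicate gene IDs")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("duplicate cell IDs")
        if self.layer_tag not in _VALID_LAYERS:
            raise ValueError(f"layer_tag must be one of {_VALID_LAYERS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.layer_tag in ("counts", "normalized") and np.any(self.values < 0):
            raise ValueError(f"{self.layer_tag} layer must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"sample_id": ["sample0"] * nc}, index=pd.Index(self.cell_ids, name="cell_id")
            )
        else:
            self.cell_meta = self.cell_meta.copy()
            if len(self.cell_meta) != nc:
                raise ValueError("cell_meta rows must align 1:1 with cell_ids")
            self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")
            if "sample_id" not in self.cell_meta.columns:
                self.cell_meta["sample_id"] = "sample0"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], [self.gene_ids[i] for i in rows],
            list(self.cell_ids), self.cell_meta, self.layer_tag,
        )

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), [self.cell_ids[j] for j in cols],
            self.cell_meta.iloc[cols], self.layer_tag,
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells × genes) view-copy."""
        import anndata

        return anndata.AnnData(
            X=self.values.T.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )

    @classmethod
    def from_anndata(cls, adata, layer_tag: LayerTag = "counts") -> "ExpressionMatrix":
        x = adata.X
        if scipy.sparse.issparse(x):
            x = x.toarray()
        return cls(np.asarray(x).T, list(adata.var_names), list(adata.obs_names),
                   adata.obs.copy(), layer_tag)


@dataclass
class GeneSetCollection:
    """Named pathway → ordered, unique gene-ID lists (GMT-backed)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def membership_counts(self) -> dict[str, int]:
        """Number of pathways containing each gene (weight denominator)."""
        counts: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class RegulonTable:
    """TF → target edges plus the catalog of genes known to be TFs."""

    edges: list[tuple[str, str, str]] = field(default_factory=list)
    tf_catalog: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for tf, target, _src in self.edges:
            if (tf, target) in seen:
                raise ValueError(f"duplicate edge ({tf}, {target})")
            seen.add((tf, target))

    @property
    def tfs(self) -> set[str]:
        return self.tf_catalog | {tf for tf, _, _ in self.edges}


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints with optional covariates."""

    table: pd.DataFrame  # index sample_id; columns time, event[, stage, smoking]

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if not np.all(t["time"] > 0):
            bad = t.index[t["time"] <= 0].tolist()
            raise ValueError(f"non-positive survival time for samples {bad}")
        if not set(np.unique(t["event"])) <= {0, 1}:
            raise ValueError("event must be coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)].copy())


@dataclass
class RunConfig:
    """All tunables of the pipeline, with defaults mirroring the study settings.

    Every stochastic operation receives an explicit seed derived from
    ``seed`` (see :mod:`nsclc_scmet.pipeline`).
    """

    seed: int = 0
    # preprocess
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_fraction: float | None = None
    n_hvg: int = 3000
    n_pcs: int = 16
    cluster_backend: str = "kmeans"
    n_clusters: int = 9
    # pathway activity
    n_perm_pathway: int = 5000
    alpha_significant: float = 0.01
    alpha_display: float = 0.05
    min_pathway_genes: int = 5
    min_gene_mean: float = 0.0
    max_zero_fraction: float = 0.95
    relative_denominator: str = "all_cells"  # or "cluster_means"
    scoring_layer: str = "normalized"
    # heterogeneity GSEA
    n_perm_gsea: int = 1000
    gsea_weight_exponent: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    # T-cell screen
    r_min: float = 0.2
    p_max: float = 0.05
    gating_layer: str = "normalized"
    zero_epsilon: float = 0.0
    # prognosis
    cv_folds: int = 10
    ties_method: str = "breslow"
    alpha_cox: float = 0.05
    horizons_days: tuple[int, ...] = (365, 730, 1460)
    standardize_expression: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "horizons_days" in raw:
            raw["horizons_days"] = tuple(raw["horizons_days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["horizons_days"] = list(data["horizons_days"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped keeping the first occurrence;
    empty gene fields are ignored.  Duplicate pathway names and lines with
    fewer than 3 columns are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            name, desc, *genes = parts
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            seen: set[str] = set()
            uniq = []
            for g in genes:
                g = g.strip()
                if g and g not in seen:
                    seen.add(g)
                    uniq.append(g)
            if not uniq:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path_or_triplet,
    dialect: str,
    *,
    sample_id: str | None = None,
    cells_in_rows: bool = False,
    layer_tag: LayerTag = "counts",
    meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix in one of the supported dialects.

    ``mtx_triplet`` expects ``(matrix.mtx, genes.tsv, barcodes.tsv)`` in the
    10x style (genes in MTX rows); ``dense_tsv`` / ``dense_csv`` expect a
    table with gene IDs in the first column and cell IDs in the header
    (``cells_in_rows=True`` for the transposed layout).  ``meta_path``
    optionally points to a TSV with a ``cell_id`` column and per-cell
    metadata (at least ``sample_id``); otherwise every cell is assigned
    ``sample_id`` (or ``"sample0"``).
    """
    if dialect == "mtx_triplet":
        mtx_path, genes_path, cells_path = path_or_triplet
        mat = scipy.io.mmread(str(mtx_path))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"MTX shape {values.shape} does not match {len(gene_ids)} genes "
                f"x {len(cell_ids)} cells"
            )
    elif dialect in ("dense_tsv", "dense_csv"):
        sep = "\t" if dialect == "dense_tsv" else ","
        df = pd.read_csv(path_or_triplet, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric entries in {path_or_triplet}: {exc}") from exc
        if cells_in_rows:
            values = values.T
            gene_ids, cell_ids = list(df.columns), list(df.index)
        else:
            gene_ids, cell_ids = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str}).set_index("cell_id")
        missing = [c for c in cell_ids if c not in meta.index]
        if missing:
            raise FormatError(f"cell metadata missing for {len(missing)} cells (e.g. {missing[:3]})")
        meta = meta.loc[[str(c) for c in cell_ids]]
    elif sample_id is not None:
        meta = pd.DataFrame({"sample_id": [sample_id] * len(cell_ids)})
    return ExpressionMatrix(values, gene_ids, cell_ids, meta, layer_tag)


def _read_id_column(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_matrix_dense(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write genes × cells dense table (gene IDs first column, cell IDs header)."""
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT)


def write_matrix_mtx(m: ExpressionMatrix, mtx_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(m.values))
    Path(genes_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


def write_cell_meta(m: ExpressionMatrix, path: str | Path) -> None:
    m.cell_meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Regulons
# ---------------------------------------------------------------------------

def read_regulons(tf_path: str | Path | None, edge_paths: Iterable[str | Path]) -> RegulonTable:
    """Read a TF catalog (one gene ID per line) and TF→target edge TSVs.

    Edge files have columns ``tf``, ``target`` and optionally ``source``.
    Edges are merged across files; duplicate (tf, target) pairs keep the
    source tag of the first occurrence.  A TF appearing only in the edge
    files is kept as a declared TF with a warning.
    """
    catalog: set[str] = set()
    if tf_path is not None and Path(tf_path).exists():
        catalog = set(_read_id_column(tf_path))

    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for path in edge_paths:
        path = Path(path)
        if not path.exists() or path.stat().st_size == 0:
            logger.warning("regulon edge file %s is empty or missing", path)
            continue
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.empty:
            logger.warning("regulon edge file %s has no rows", path)
            continue
        cols = {c.lower(): c for c in df.columns}
        tf_col, tg_col = cols.get("tf"), cols.get("target")
        if tf_col is None or tg_col is None:
            raise FormatError(f"{path}: expected columns 'tf' and 'target'")
        src_col = cols.get("source")
        for _, row in df.iterrows():
            tf, target = str(row[tf_col]), str(row[tg_col])
            src = str(row[src_col]) if src_col else path.stem
            if (tf, target) in seen:
                continue
            seen.add((tf, target))
            if catalog and tf not in catalog:
                logger.warning("TF %s not in catalog; kept as declared TF", tf)
            edges.append((tf, target, src))
    return RegulonTable(edges, catalog)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def read_clinical(
    path: str | Path,
    *,
    sample_col: str = "sample_id",
    time_col: str = "time",
    event_col: str = "event",
    event_map: Mapping[str, int] | None = None,
) -> ClinicalTable:
    """Read a clinical TSV; rows with missing time/event are dropped and logged.

    ``event_map`` maps string codes (e.g. ``dead``/``alive``) to 1/0.
    Negative or zero survival times are an error naming the sample.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.rename(columns={sample_col: "sample_id", time_col: "time", event_col: "event"})
    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_clinical: dropped %d rows with missing time/event", dropped)
    if df.empty:
        raise FormatError(f"{path}: no usable rows after dropping missing time/event")
    if event_map is not None:
        df["event"] = df["event"].map(lambda v: event_map.get(str(v), v))
    df["event"] = df["event"].astype(int)
    df["time"] = df["time"].astype(float)
    bad = df.loc[df["time"] <= 0, "sample_id"].tolist()
    if bad:
        raise FormatError(f"{path}: non-positive survival time for samples {bad}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = True) -> None:
    """Package-wide TSV writer: fixed separator, 6 significant digits."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
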