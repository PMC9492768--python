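"""Single-cell expression matrices: loading, QC filtering, binarization, subsetting.

The Boolean modelling pipeline consumes a cells x genes matrix together
with per-cell metadata (cluster label, subject, contrast group).  Quality
control follows the standard droplet-data recipe: drop cells expressing too
few or too many genes or with a high mitochondrial fraction, then drop
genes detected in too few of the surviving cells.

Binarization converts expression to presence/absence states.  The default
is the nonzero indicator — droplet scRNA-seq is strongly bimodal, so a
detected transcript is read as "on" — with per-gene threshold and
nonzero-median alternatives available.  The continuous matrix is retained
alongside the binary states because the contrast statistics (relative
abundance and dispersion) are computed on continuous expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("cluster", "subject", "group")


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression with aligned per-cell metadata."""

    values: np.ndarray  # (n_cells, n_genes), float
    cell_ids: list[str]
    gene_symbols: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        nc, ng = self.values.shape
        if len(self.cell_ids) != nc:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {nc} rows")
        if len(self.gene_symbols) != ng:
            raise ValueError(f"{len(self.gene_symbols)} gene symbols for {ng} columns")
        if len(set(self.gene_symbols)) != ng:
            raise ValueError("gene symbols must be unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        elif list(self.metadata.index) != list(self.cell_ids):
            self.metadata = self.metadata.reindex(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_symbols.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def take_cells(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            metadata=self.metadata.iloc[idx],
        )

    def take_genes(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return replace(
            self,
            values=self.values[:, idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.gene_symbols
        ).to_csv(path)


@dataclass
class BinaryExpressionMatrix(ExpressionMatrix):
    """Binary 0/1 states plus the continuous source matrix they came from."""

    continuous: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("binary states must be 0/1")
        self.values = self.values.astype(np.int8)
        if self.continuous is not None and self.continuous.values.shape != self.values.shape:
            raise ValueError("continuous matrix shape differs from binary states")

    @property
    def states(self) -> np.ndarray:
        return self.values

    def cell_state(self, i: int, genes: Sequence[str]) -> tuple[int, ...]:
        """Binary state of cell ``i`` restricted to ``genes`` (given order)."""
        cols = [self.gene_index(g) for g in genes]
        return tuple(int(v) for v in self.values[i, cols])

    def states_for(self, genes: Sequence[str]) -> np.ndarray:
        cols = [self.gene_index(g) for g in genes]
        return self.values[:, cols]

    def take_cells(self, idx: Sequence[int]) -> "BinaryExpressionMatrix":
        idx = list(idx)
        return BinaryExpressionMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_symbols=list(self.gene_symbols),
            metadata=self.metadata.iloc[idx],
            continuous=self.continuous.take_cells(idx)
            if self.continuous is not None
            else None,
        )

    def take_genes(self, idx: Sequence[int]) -> "BinaryExpressionMatrix":
        idx = list(idx)
        return BinaryExpressionMatrix(
            values=self.values[:, idx],
            cell_ids=list(self.cell_ids),
            gene_symbols=[self.gene_symbols[i] for i in idx],
            metadata=self.metadata,
            continuous=self.continuous.take_genes(idx)
            if self.continuous is not None
            else None,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.gene_symbols
        ).to_csv(path, sep="\t")


def concat_genes(
    b1: BinaryExpressionMatrix, b2: BinaryExpressionMatrix
) -> BinaryExpressionMatrix:
    """Join two binary matrices over the same cells, stacking their genes.

    Useful for analyzing several disjoint pathways against one cell
    population; cell ids and metadata come from the first matrix and the
    gene sets must not overlap.
    """
    if b1.n_cells != b2.n_cells:
        raise ValueError("matrices cover different numbers of cells")
    if set(b1.gene_symbols) & set(b2.gene_symbols):
        raise ValueError("gene sets overlap")
    genes = b1.gene_symbols + b2.gene_symbols
    cont = None
    if b1.continuous is not None and b2.continuous is not None:
        cont = ExpressionMatrix(
            values=np.hstack([b1.continuous.values, b2.continuous.values]),
            cell_ids=list(b1.cell_ids),
            gene_symbols=genes,
            metadata=b1.metadata.copy(),
        )
    return BinaryExpressionMatrix(
        values=np.hstack([b1.values, b2.values]),
        cell_ids=list(b1.cell_ids),
        gene_symbols=genes,
        metadata=b1.metadata.copy(),
        continuous=cont,
    )


def load_matrix(
    path,
    fmt: str | None = None,
    orientation: str = "cells-by-genes",
    metadata_path=None,
    features_path=None,
    barcodes_path=None,
) -> ExpressionMatrix:
    """Load an expression matrix from MatrixMarket or dense CSV/TSV.

    MTX input follows the 10x triplet convention: the matrix file plus
    ``features.tsv`` (gene symbols, first or second column) and
    ``barcodes.tsv`` sidecars in the same directory, genes x cells on disk
    (override with ``orientation="cells-by-genes"`` if already transposed).
    CSV/TSV input has a header row of gene names and one row per cell.
    Metadata is a CSV keyed by cell barcode with columns cluster, subject,
    group.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix in (".mtx", ".mm") else "csv"
    if fmt == "mtx":
        mat = sparse.csr_matrix(spio.mmread(path))
        features_path = features_path or _sidecar(path, ("features.tsv", "genes.tsv"))
        barcodes_path = barcodes_path or _sidecar(path, ("barcodes.tsv",))
        genes = _read_sidecar_column(features_path)
        cells = _read_sidecar_column(barcodes_path, column=0)
        if orientation == "genes-by-cells":
            mat = mat.T
            genes, cells = genes, cells
        nc, ng = mat.shape
        if len(cells) != nc or len(genes) != ng:
            raise ValueError(
                f"matrix is {nc} x {ng} after orientation but sidecars list "
                f"{len(cells)} barcodes and {len(genes)} features"
            )
        values = np.asarray(mat.todense(), dtype=float)
    elif fmt in ("csv", "tsv"):
        sep = "\t" if fmt == "tsv" or path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes-by-cells":
            df = df.T
        values = df.to_numpy(dtype=float)
        cells = [str(c) for c in df.index]
        genes = [str(g) for g in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    genes = [g.upper() for g in genes]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell"))
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, index_col=0)
        meta.index = meta.index.astype(str)
    return ExpressionMatrix(
        values=values, cell_ids=list(cells), gene_symbols=genes, metadata=meta
    )


def _sidecar(mtx_path: Path, names: tuple[str, ...]) -> Path:
    for n in names:
        p = mtx_path.with_name(n)
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no sidecar {' / '.join(names)} next to {mtx_path}"
    )


def _read_sidecar_column(path, column: int | None = None) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    if column is None:
        # 10x features.tsv: ensembl id, symbol, type — prefer the symbol column
        column = 1 if df.shape[1] > 1 else 0
    return [str(v) for v in df.iloc[:, column]]


def qc_filter(
    m: ExpressionMatrix,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito_frac: float = 0.05,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Standard droplet QC: cell filters first, then gene detection filter.

    Cells expressing fewer than ``min_genes`` or more than ``max_genes``
    genes, or whose mitochondrial-gene counts exceed ``max_mito_frac`` of
    their total, are removed; genes detected (value > 0) in fewer than
    ``min_cells_per_gene`` surviving cells are then removed.
    """
    detected = m.values > 0
    genes_per_cell = detected.sum(axis=1)
    mito_cols = np.array(
        [g.upper().startswith(mito_prefix.upper()) for g in m.gene_symbols]
    )
    totals = m.values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, m.values[:, mito_cols].sum(axis=1) / np.maximum(totals, 1e-12), 0.0
        )
    keep_cells = (
        (genes_per_cell >= min_genes)
        & (genes_per_cell <= max_genes)
        & (mito_frac <= max_mito_frac)
    )
    if not keep_cells.any():
        raise ValueError(
            "QC removed every cell; review min_genes/max_genes/max_mito_frac "
            "against the data's depth"
        )
    out = m.take_cells(np.flatnonzero(keep_cells))
    cells_per_gene = (out.values > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = out.take_genes(np.flatnonzero(keep_genes))
    logger.info(
        "QC: cells %d -> %d, genes %d -> %d",
        m.n_cells, out.n_cells, m.n_genes, out.n_genes,
    )
    return out


def binarize(
    m: ExpressionMatrix, method: str = "nonzero", threshold: float | None = None
) -> BinaryExpressionMatrix:
    """Convert expression to 0/1 states, retaining the continuous matrix.

    Methods: ``nonzero`` (state 1 iff value > 0, the default), ``threshold``
    (1 iff value > t), ``median`` (1 iff value > the gene's median over its
    nonzero values; all-zero genes stay 0).
    """
    if np.any(m.values < 0):
        raise ValueError("negative expression values")
    if method == "nonzero":
        states = (m.values > 0).astype(np.int8)
    elif method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires a threshold value")
        states = (m.values > threshold).astype(np.int8)
    elif method == "median":
        states = np.zeros_like(m.values, dtype=np.int8)
        for j in range(m.n_genes):
            col = m.values[:, j]
            nz = col[col > 0]
            if nz.size:
                states[:, j] = (col > np.median(nz)).astype(np.int8)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryExpressionMatrix(
        values=states,
        cell_ids=list(m.cell_ids),
        gene_symbols=list(m.gene_symbols),
        metadata=m.metadata.copy(),
        continuous=m,
    )


def subset(
    m: BinaryExpressionMatrix,
    cluster: str | None = None,
    groups: tuple[str, str] | None = None,
) -> BinaryExpressionMatrix:
    """Restrict to one cluster and optionally to a two-group contrast."""
    mask = np.ones(m.n_cells, dtype=bool)
    if cluster is not None:
        if "cluster" not in m.metadata.columns:
            raise ValueError("metadata has no 'cluster' column")
        labels = m.metadata["cluster"].astype(str).to_numpy()
        if str(cluster) not in set(labels):
            raise ValueError(f"cluster {cluster!r} not present in metadata")
        mask &= labels == str(cluster)
    if groups is not None:
        if "group" not in m.metadata.columns:
            raise ValueError("metadata has no 'group' column")
        glabels = m.metadata["group"].astype(str).to_numpy()
        mask &= np.isin(glabels, [str(g) for g in groups])
        for g in groups:
            if not ((glabels == str(g)) & mask).any():
                raise ValueError(f"group {g!r} has no cells after subsetting")
    if not mask.any():
        raise ValueError("subset selects no cells")
    out = m.take_cells(np.flatnonzero(mask))
    if groups is not None:
        sizes = out.metadata["group"].value_counts().to_dict()
        logger.info("subset group sizes: %s", sizes)
    return out
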