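"""Loading, validation and preprocessing of barcoded count data.

The central container is :class:`CellDataset`: a cells × genes spliced count
matrix (optionally a matched unspliced matrix), one lineage barcode and one
observation day per cell, and optional cell-type labels.  The per-cell scale
``chi`` — the mean spliced count across genes — multiplies the decoder's
per-gene Poisson rate, so every retained cell must have at least one count.

Preprocessing follows the workflow used on the hematopoiesis lineage-tracing
data: select highly variable genes by mean-binned normalized dispersion on
log-normalized counts (raw counts stay the model input), then keep lineages
with strictly more than ``min_cells`` cells that include the earliest
observation day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CellDataset",
    "load_dataset",
    "select_highly_variable_genes",
    "filter_lineages",
]


@dataclass
class CellDataset:
    """Validated single-cell count dataset with lineage metadata.

    Parameters
    ----------
    spliced
        Non-negative integer count matrix, cells × genes.
    barcode
        Lineage barcode per cell (clonal membership).
    day
        Observation day per cell (non-negative integer).
    gene_names, cell_ids
        Identifiers for columns and rows.
    unspliced
        Optional nascent-mRNA counts, same shape as ``spliced``.
    cell_type
        Optional per-cell annotation.
    """

    spliced: np.ndarray
    barcode: np.ndarray
    day: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    unspliced: np.ndarray | None = None
    cell_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spliced = _validate_counts(np.asarray(self.spliced), "spliced")
        if self.unspliced is not None:
            self.unspliced = _validate_counts(np.asarray(self.unspliced), "unspliced")
            if self.unspliced.shape != self.spliced.shape:
                raise ValueError(
                    f"unspliced shape {self.unspliced.shape} != spliced shape "
                    f"{self.spliced.shape}"
                )
        n, g = self.spliced.shape
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        day = np.asarray(self.day)
        if not np.all(np.equal(np.mod(day, 1), 0)):
            raise ValueError("observation days must be integers (no rounding applied)")
        self.day = day.astype(np.int64)
        if np.any(self.day < 0):
            raise ValueError("observation days must be non-negative")
        for name, arr in [("barcode", self.barcode), ("day", self.day),
                          ("cell_ids", self.cell_ids)]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n} cells")
        if len(self.gene_names) != g:
            raise ValueError(
                f"gene_names has length {len(self.gene_names)}, expected {g}"
            )
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != n:
                raise ValueError("cell_type length mismatch")
        totals = self.spliced.sum(axis=1)
        if np.any(totals == 0):
            bad = list(self.cell_ids[totals == 0][:5])
            raise ValueError(
                f"cells with zero total counts are not allowed (chi must be "
                f"positive); offending cells include {bad}"
            )

    # -- derived -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    @property
    def chi(self) -> np.ndarray:
        """Per-cell scale: mean spliced count across genes (always > 0)."""
        return self.spliced.mean(axis=1)

    @property
    def days(self) -> np.ndarray:
        """Sorted unique observation days."""
        return np.unique(self.day)

    def lineage_sizes(self) -> pd.Series:
        return pd.Series(self.barcode).value_counts()

    # -- subsetting ---------------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "CellDataset":
        index = np.asarray(index)
        return replace(
            self,
            spliced=self.spliced[index],
            unspliced=None if self.unspliced is None else self.unspliced[index],
            barcode=self.barcode[index],
            day=self.day[index],
            cell_ids=self.cell_ids[index],
            cell_type=None if self.cell_type is None else self.cell_type[index],
        )

    def subset_genes(self, index: np.ndarray) -> "CellDataset":
        index = np.asarray(index)
        return replace(
            self,
            spliced=self.spliced[:, index],
            unspliced=None if self.unspliced is None else self.unspliced[:, index],
            gene_names=self.gene_names[index],
        )

    # -- interop ------------------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {"barcode": self.barcode.astype(str), "day": self.day},
            index=self.cell_ids.astype(str),
        )
        if self.cell_type is not None:
            obs["cell_type"] = self.cell_type.astype(str)
        adata = ad.AnnData(
            X=self.spliced.astype(np.float64),
            obs=obs,
            var=pd.DataFrame(index=self.gene_names.astype(str)),
        )
        if self.unspliced is not None:
            adata.layers["unspliced"] = self.unspliced.astype(np.float64)
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "CellDataset":
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        unspliced = None
        if "unspliced" in adata.layers:
            U = adata.layers["unspliced"]
            unspliced = U.toarray() if scipy.sparse.issparse(U) else np.asarray(U)
        return cls(
            spliced=np.asarray(X),
            unspliced=unspliced,
            barcode=adata.obs["barcode"].to_numpy(),
            day=adata.obs["day"].to_numpy(),
            cell_type=(adata.obs["cell_type"].to_numpy()
                       if "cell_type" in adata.obs else None),
            gene_names=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
        )

    def write_h5ad(self, path: str | Path) -> None:
        self.to_anndata().write_h5ad(Path(path))


def _validate_counts(x: np.ndarray, name: str) -> np.ndarray:
    if x.ndim != 2:
        raise ValueError(f"{name} matrix must be 2-dimensional, got ndim={x.ndim}")
    if np.any(x < 0):
        raise ValueError(f"{name} counts contain negative entries")
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError(f"{name} counts contain non-integer entries")
    return np.asarray(x, dtype=np.int64)


def _read_counts(path: Path) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Read a counts file; returns (matrix, cell_ids, gene_names).

    MTX matrices use companion ``<stem>.barcodes.txt`` / ``<stem>.genes.txt``
    files (one ID per line, cells = rows); dense CSV/TSV carry cell IDs in the
    first column and gene names in the header.
    """
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        cells = genes = None
        bc = path.with_suffix(".barcodes.txt")
        gn = path.with_suffix(".genes.txt")
        if not bc.exists():
            bc = path.parent / "barcodes.txt"
        if not gn.exists():
            gn = path.parent / "genes.txt"
        if bc.exists():
            cells = np.loadtxt(bc, dtype=str, ndmin=1)
        if gn.exists():
            genes = np.loadtxt(gn, dtype=str, ndmin=1)
        return mat, cells, genes
    if suffix in {".csv", ".tsv", ".txt"}:
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return df.to_numpy(), df.index.to_numpy().astype(str), df.columns.to_numpy().astype(str)
    if suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        return np.asarray(X), adata.obs_names.to_numpy().astype(str), adata.var_names.to_numpy().astype(str)
    raise ValueError(f"unsupported counts format: {path}")


def load_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    unspliced_path: str | Path | None = None,
) -> CellDataset:
    """Assemble a :class:`CellDataset` from counts and a metadata table.

    The metadata CSV must have columns ``cell_id``, ``barcode`` and ``day``
    (optionally ``cell_type``); its row order defines the cell order of the
    returned dataset.  Cells present in only one of counts/metadata are
    dropped with a warning; an empty intersection is an error.
    """
    counts_path = Path(counts_path)
    counts, cell_ids, gene_names = _read_counts(counts_path)
    counts = _validate_counts(counts, "spliced")
    meta = pd.read_csv(metadata_path)
    required = {"cell_id", "barcode", "day"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    meta = meta.astype({"cell_id": str})

    if cell_ids is None:
        if len(meta) != counts.shape[0]:
            raise ValueError(
                f"counts have {counts.shape[0]} rows but metadata has "
                f"{len(meta)} cells and no cell IDs accompany the matrix"
            )
        cell_ids = meta["cell_id"].to_numpy()
    if gene_names is None:
        gene_names = np.array([f"gene_{j}" for j in range(counts.shape[1])])

    counts_df_index = pd.Index(cell_ids)
    if counts_df_index.has_duplicates:
        raise ValueError("duplicate cell IDs in counts")
    keep = meta["cell_id"].isin(set(cell_ids))
    dropped_meta = meta.loc[~keep, "cell_id"].tolist()
    if dropped_meta:
        logger.warning(
            "%d metadata cells absent from counts were dropped: %s",
            len(dropped_meta), dropped_meta[:5],
        )
    meta = meta.loc[keep]
    extra_counts = sorted(set(cell_ids) - set(meta["cell_id"]))
    if extra_counts:
        logger.warning(
            "%d cells in counts absent from metadata were dropped: %s",
            len(extra_counts), extra_counts[:5],
        )
    if meta.empty:
        raise ValueError(
            "no overlap between counts cell IDs and metadata cell_id column"
        )
    row_of = {c: i for i, c in enumerate(cell_ids)}
    order = np.array([row_of[c] for c in meta["cell_id"]])

    unspliced = None
    if unspliced_path is not None:
        u_mat, u_cells, _ = _read_counts(Path(unspliced_path))
        if u_cells is not None:
            u_of = {c: i for i, c in enumerate(u_cells)}
            missing_u = [c for c in meta["cell_id"] if c not in u_of]
            if missing_u:
                raise ValueError(
                    f"unspliced counts are missing cells: {missing_u[:5]}"
                )
            unspliced = u_mat[np.array([u_of[c] for c in meta["cell_id"]])]
        else:
            unspliced = u_mat[order]
    elif counts_path.suffix.lower() == ".h5ad":
        adata = ad.read_h5ad(counts_path)
        if "unspliced" in adata.layers:
            U = adata.layers["unspliced"]
            U = U.toarray() if scipy.sparse.issparse(U) else np.asarray(U)
            unspliced = U[order]

    spliced = counts[order]
    totals = spliced.sum(axis=1)
    if np.any(totals == 0):
        zero_ids = meta["cell_id"].to_numpy()[totals == 0]
        logger.warning("dropping %d all-zero cells: %s", len(zero_ids), zero_ids[:5])
        nz = totals > 0
        spliced = spliced[nz]
        unspliced = None if unspliced is None else unspliced[nz]
        meta = meta.loc[nz]
    return CellDataset(
        spliced=spliced,
        unspliced=unspliced,
        barcode=meta["barcode"].to_numpy(),
        day=meta["day"].to_numpy(),
        cell_type=(meta["cell_type"].to_numpy() if "cell_type" in meta else None),
        gene_names=gene_names,
        cell_ids=meta["cell_id"].to_numpy(),
    )


def normalized_dispersion(counts: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion of log-normalized counts.

    Counts are scaled per cell to the median library size and log1p
    transformed; per-gene dispersion (variance / mean) is then z-scored
    within ``n_bins`` equal-frequency bins of the per-gene mean.
    """
    totals = counts.sum(axis=1).astype(np.float64)
    target = float(np.median(totals))
    logX = np.log1p(counts * (target / totals)[:, None])
    mu = logX.mean(axis=0)
    var = logX.var(axis=0, ddof=1) if counts.shape[0] > 1 else np.zeros_like(mu)
    disp = np.divide(var, mu, out=np.zeros_like(var), where=mu > 0)
    bins = pd.qcut(mu, q=min(n_bins, len(np.unique(mu))), duplicates="drop",
                   labels=False)
    normed = np.zeros_like(disp)
    for b in np.unique(bins):
        in_bin = bins == b
        d = disp[in_bin]
        sd = d.std(ddof=1) if in_bin.sum() > 1 else 0.0
        normed[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    return normed


def select_highly_variable_genes(ds: CellDataset, n_top: int = 1000,
                                 n_bins: int = 20) -> CellDataset:
    """Restrict the dataset to the ``n_top`` most variable genes.

    Variability is ranked by mean-binned normalized dispersion computed on
    log-normalized counts; the returned dataset keeps the raw counts of the
    selected genes (the model consumes raw counts).
    """
    if n_top > ds.n_genes:
        raise ValueError(f"n_top={n_top} exceeds the {ds.n_genes} genes present")
    score = normalized_dispersion(ds.spliced, n_bins=n_bins)
    # stable ranking: ties broken by gene index
    order = np.lexsort((np.arange(ds.n_genes), -score))
    keep = np.sort(order[:n_top])
    return ds.subset_genes(keep)


def filter_lineages(ds: CellDataset, min_cells: int = 20,
                    require_day: int | None = None) -> CellDataset:
    """Keep cells whose lineage has > ``min_cells`` members (and, if given,
    at least one cell observed at ``require_day``)."""
    sizes = ds.lineage_sizes()
    ok = set(sizes.index[sizes > min_cells])
    if require_day is not None:
        with_day = set(np.unique(ds.barcode[ds.day == require_day]))
        ok &= with_day
    mask = np.array([b in ok for b in ds.barcode])
    if not mask.any():
        raise ValueError(
            f"no lineage passes the filters (min_cells={min_cells}, "
            f"require_day={require_day}); lower the thresholds"
        )
    return ds.subset_cells(mask)
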