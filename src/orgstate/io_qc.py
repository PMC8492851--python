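"""Count-matrix I/O, quality control, normalization, HVG selection and scaling.

Count matrices are held in :class:`anndata.AnnData` with raw integer counts in
``.X`` (cells x genes, CSR), optional ``spliced``/``unspliced`` layers, cell
metadata in ``.obs`` and gene metadata in ``.var``.  On disk the package uses
the 10x triplet convention: a Matrix Market file (genes x cells) plus barcode
and feature tables, plain or gzipped.

QC follows the organoid scRNA-seq protocol: cells with fewer than 200 detected
genes, more than 100,000 reads or more than 15% mitochondrial counts are
excluded, and genes detected in fewer than 3 cells are dropped.  Normalization
is log1p of counts scaled to a fixed per-cell total (10,000 by default).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError, EmptyResultError, FormatError, NormalizationError

__all__ = [
    "read_counts_10x",
    "write_counts_10x",
    "compute_qc_metrics",
    "qc_filter",
    "QCReport",
    "lognormalize",
    "select_hvg",
    "scale_center",
    "ScaledMatrix",
]

MITO_PREFIX = "MT-"

_LAYER_FILES = {"spliced": "spliced.mtx", "unspliced": "unspliced.mtx"}


def _open_maybe_gz(base: Path):
    """Return an open binary handle for ``base`` or ``base + '.gz'``."""
    if base.exists():
        return open(base, "rb")
    gz = base.with_name(base.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rb")
    return None


def _read_table(directory: Path, names: tuple[str, ...]) -> pd.DataFrame | None:
    for name in names:
        fh = _open_maybe_gz(directory / name)
        if fh is not None:
            with fh:
                return pd.read_csv(fh, sep="\t", header=None, dtype=str)
    return None


def _read_mtx(directory: Path, name: str) -> sp.csr_matrix | None:
    fh = _open_maybe_gz(directory / name)
    if fh is None:
        return None
    with fh:
        m = scipy.io.mmread(fh)
    return sp.csr_matrix(m)


def read_counts_10x(path: str | Path) -> ad.AnnData:
    """Read a 10x-convention directory into an AnnData (cells x genes).

    Expects ``matrix.mtx`` (genes x cells triplets), ``barcodes.tsv`` and
    ``features.tsv`` (or ``genes.tsv``), each optionally gzipped.  Parallel
    ``spliced.mtx`` / ``unspliced.mtx`` triplet files, when present, are
    loaded as layers.  A ``cell_meta.tsv`` written by :func:`write_counts_10x`
    restores extra per-cell metadata.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    matrix = _read_mtx(directory, "matrix.mtx")
    if matrix is None:
        raise FormatError(f"no matrix.mtx(.gz) in {directory}")
    barcodes = _read_table(directory, ("barcodes.tsv",))
    features = _read_table(directory, ("features.tsv", "genes.tsv"))
    if barcodes is None or features is None:
        raise FormatError(f"missing barcodes/features table in {directory}")

    n_genes, n_cells = matrix.shape
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcode table has {len(barcodes)} rows but matrix has {n_cells} columns"
        )
    if len(features) != n_genes:
        raise FormatError(
            f"feature table has {len(features)} rows but matrix has {n_genes} rows"
        )

    symbols = features.iloc[:, 1] if features.shape[1] > 1 else features.iloc[:, 0]
    var = pd.DataFrame(
        {"gene_id": features.iloc[:, 0].to_numpy()},
        index=pd.Index(symbols.to_numpy(), name="symbol"),
    )
    var["is_mito"] = var.index.str.startswith(MITO_PREFIX)
    obs = pd.DataFrame(index=pd.Index(barcodes.iloc[:, 0].to_numpy(), name="barcode"))

    X = sp.csr_matrix(matrix.T)
    X.sum_duplicates()
    adata = ad.AnnData(X=X, obs=obs, var=var)

    for layer, fname in _LAYER_FILES.items():
        lm = _read_mtx(directory, fname)
        if lm is not None:
            if lm.shape != (n_genes, n_cells):
                raise FormatError(f"{fname} shape {lm.shape} != matrix shape")
            adata.layers[layer] = sp.csr_matrix(lm.T)

    meta = directory / "cell_meta.tsv"
    if meta.exists():
        df = pd.read_csv(meta, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        adata.obs = adata.obs.join(df)
    return adata


def write_counts_10x(adata: ad.AnnData, path: str | Path, gzip_files: bool = False) -> None:
    """Write an AnnData as a 10x-convention triplet directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    def _write_mtx(name, matrix):
        target = directory / (name + suffix)
        coo = sp.coo_matrix(matrix.T)  # genes x cells on disk
        if gzip_files:
            with gzip.open(target, "wb") as fh:
                scipy.io.mmwrite(fh, coo)
        else:
            scipy.io.mmwrite(str(target), coo)

    _write_mtx("matrix.mtx", adata.X)
    for layer in ("spliced", "unspliced"):
        if layer in adata.layers:
            _write_mtx(_LAYER_FILES[layer], adata.layers[layer])

    def _write_text(name, text):
        target = directory / (name + suffix)
        data = text.encode()
        if gzip_files:
            with gzip.open(target, "wb") as fh:
                fh.write(data)
        else:
            target.write_bytes(data)

    _write_text("barcodes.tsv", "\n".join(adata.obs_names) + "\n")
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    lines = [
        f"{gid}\t{sym}\tGene Expression" for gid, sym in zip(gene_ids, adata.var_names)
    ]
    _write_text("features.tsv", "\n".join(lines) + "\n")

    extra = adata.obs.drop(columns=[c for c in adata.obs.columns if c.startswith("_")])
    if extra.shape[1] > 0:
        extra.to_csv(directory / "cell_meta.tsv", sep="\t")


def compute_qc_metrics(adata: ad.AnnData, overwrite: bool = False) -> ad.AnnData:
    """Fill ``total_reads``, ``n_genes_detected``, ``mito_fraction`` in ``.obs``.

    Existing columns are kept unless ``overwrite`` — QC metrics are frozen at
    first computation so that repeated filtering judges cells on the same
    numbers.
    """
    X = sp.csr_matrix(adata.X)
    if "is_mito" not in adata.var:
        adata.var["is_mito"] = adata.var_names.str.startswith(MITO_PREFIX)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if overwrite or "total_reads" not in adata.obs:
        adata.obs["total_reads"] = totals
    if overwrite or "n_genes_detected" not in adata.obs:
        adata.obs["n_genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    if overwrite or "mito_fraction" not in adata.obs:
        mito = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        adata.obs["mito_fraction"] = frac
    return adata


@dataclass
class QCReport:
    """Per-criterion removal counts from one :func:`qc_filter` call."""

    n_cells_in: int = 0
    n_cells_kept: int = 0
    n_genes_in: int = 0
    n_genes_kept: int = 0
    cells_low_genes: int = 0
    cells_high_reads: int = 0
    cells_high_mito: int = 0
    genes_low_cells: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_cells_removed(self) -> int:
        return self.n_cells_in - self.n_cells_kept

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "cells_in": self.n_cells_in,
            "cells_kept": self.n_cells_kept,
            "cells_removed": self.n_cells_removed,
            "cells_low_genes": self.cells_low_genes,
            "cells_high_reads": self.cells_high_reads,
            "cells_high_mito": self.cells_high_mito,
            "genes_in": self.n_genes_in,
            "genes_kept": self.n_genes_kept,
            "genes_low_cells": self.genes_low_cells,
        }
        return pd.DataFrame({"count": rows})


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    min_cells: int = 3,
    max_reads: float = 100_000,
    max_mito: float = 0.15,
) -> tuple[ad.AnnData, QCReport]:
    """Apply the cell and gene quality filters.

    Cells are kept when ``n_genes_detected >= min_genes``,
    ``total_reads <= max_reads`` and ``mito_fraction <= max_mito`` (the read
    and mitochondrial thresholds exclude strictly greater values, so a cell at
    exactly 100,000 reads or 15.0% mitochondrial counts survives).  Genes are
    then kept when detected in at least ``min_cells`` of the retained cells.
    Cell metrics are frozen at first computation (see
    :func:`compute_qc_metrics`), which makes the filter idempotent.
    """
    compute_qc_metrics(adata)
    obs = adata.obs
    low_genes = obs["n_genes_detected"].to_numpy() < min_genes
    high_reads = obs["total_reads"].to_numpy() > max_reads
    high_mito = obs["mito_fraction"].to_numpy() > max_mito
    keep_cells = ~(low_genes | high_reads | high_mito)

    report = QCReport(
        n_cells_in=adata.n_obs,
        n_genes_in=adata.n_vars,
        cells_low_genes=int(low_genes.sum()),
        cells_high_reads=int(high_reads.sum()),
        cells_high_mito=int(high_mito.sum()),
        thresholds=dict(
            min_genes=min_genes, min_cells=min_cells, max_reads=max_reads, max_mito=max_mito
        ),
    )
    if not keep_cells.any():
        report.n_cells_kept = 0
        report.n_genes_kept = 0
        raise EmptyResultError("all cells removed by QC filters", report=report)

    sub = adata[keep_cells]
    detected = np.asarray((sp.csr_matrix(sub.X) > 0).sum(axis=0)).ravel()
    keep_genes = detected >= min_cells
    report.genes_low_cells = int((~keep_genes).sum())
    report.n_cells_kept = int(keep_cells.sum())
    report.n_genes_kept = int(keep_genes.sum())
    return sub[:, keep_genes].copy(), report


def lognormalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Log-normalize counts: ``ln(1 + count / cell_total * scale_factor)``.

    Returns a new AnnData whose ``.X`` holds the normalized values (sparse,
    zeros preserved); raw counts are kept in ``.layers['counts']`` and the
    scale factor in ``.uns['scale_factor']``.
    """
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be positive")
    X = sp.csr_matrix(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise NormalizationError(f"cell {bad!r} has zero total counts; run qc_filter first")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.layers["counts"] = sp.csr_matrix(adata.X).copy()
    for layer in ("spliced", "unspliced"):
        if layer in adata.layers:
            out.layers[layer] = adata.layers[layer].copy()
    out.uns["scale_factor"] = float(scale_factor)
    return out


def select_hvg(nm: ad.AnnData, n: int = 2000, clip: str | float = "auto") -> np.ndarray:
    """Flag the ``n`` most variable genes by vst-style standardized variance.

    Per-gene mean and variance are computed on raw counts
    (``nm.layers['counts']``); the mean-variance trend is fit as a quadratic
    in log10 space; counts standardized under the trend are clipped (default
    ``sqrt(n_cells)``) and the variance of the clipped values ranks genes.
    The mask is stored in ``nm.var['highly_variable']``.
    """
    if n > nm.n_vars:
        raise ConfigurationError(f"requested {n} HVGs but only {nm.n_vars} genes present")
    counts = nm.layers.get("counts")
    if counts is None:
        counts = nm.X
    counts = sp.csr_matrix(counts).astype(np.float64)
    n_cells = counts.shape[0]

    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = counts.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    ok = (mean > 0) & (var > 0)
    std_var = np.zeros(nm.n_vars)
    if ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        coef = np.polyfit(lm, lv, deg=2)
        pred_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
        clip_val = np.sqrt(n_cells) if clip == "auto" else float(clip)

        # variance of clipped standardized counts, computed sparsely:
        # nonzero entries contribute z = (x - mu)/sd, zeros contribute -mu/sd
        idx = np.flatnonzero(ok)
        csc = counts.tocsc()
        for col, mu, sd in zip(idx, mean[ok], pred_sd):
            x = csc.data[csc.indptr[col] : csc.indptr[col + 1]]
            z = np.clip((x - mu) / sd, -clip_val, clip_val)
            z0 = np.clip(-mu / sd, -clip_val, clip_val)
            nnz = x.size
            s1 = z.sum() + z0 * (n_cells - nnz)
            s2 = (z**2).sum() + z0**2 * (n_cells - nnz)
            std_var[col] = (s2 - s1**2 / n_cells) / max(n_cells - 1, 1)

    order = np.argsort(-std_var, kind="stable")
    mask = np.zeros(nm.n_vars, dtype=bool)
    mask[order[:n]] = True
    nm.var["highly_variable"] = mask
    nm.var["variance_standardized"] = std_var
    return mask


@dataclass
class ScaledMatrix:
    """Z-scored HVG expression with the statistics used to produce it."""

    values: np.ndarray  # cells x HVGs, dense
    gene_names: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    cell_names: np.ndarray

    @property
    def shape(self):
        return self.values.shape


def scale_center(nm: ad.AnnData, clip: float = 10.0) -> ScaledMatrix:
    """Center and scale HVG expression to zero mean / unit variance per gene.

    Uses the population (``n``) standard deviation; values are clipped to
    ``±clip``.  Zero-variance genes scale to all zeros with a warning.
    """
    if "highly_variable" not in nm.var:
        raise ConfigurationError("run select_hvg before scale_center")
    mask = nm.var["highly_variable"].to_numpy()
    X = np.asarray(sp.csr_matrix(nm.X)[:, mask].todense(), dtype=np.float64)
    means = X.mean(axis=0)
    stds = X.std(axis=0)  # population SD
    zero = stds == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance HVG(s) scaled to 0")
    safe = np.where(zero, 1.0, stds)
    values = np.clip((X - means) / safe, -clip, clip)
    values[:, zero] = 0.0
    return ScaledMatrix(
        values=values,
        gene_names=nm.var_names[mask].to_numpy(),
        means=means,
        stds=stds,
        cell_names=nm.obs_names.to_numpy(),
    )
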