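"""Cell calling, per-cell QC metrics, filtering and log-normalization.

The QC filters follow a strict reading of the study design they
implement: cells with fewer than 200 or more than 5000 expressed genes,
more than 30,000 UMIs, or mitochondrial content above 30% are removed,
so cells sitting exactly on a bound survive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

logger = logging.getLogger(__name__)

MITO_REGEX = r"^MT-"


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 5000
    max_umis: int = 30_000
    max_mito_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def call_cells_knee(barcode_umi_totals, min_barcodes: int = 10) -> np.ndarray:
    """Knee-based cell calling on the barcode-rank curve.

    The knee is the point of the descending log10(rank)-log10(total)
    curve with maximal perpendicular distance to the chord joining the
    curve's endpoints, ties broken toward higher totals.  All barcodes
    with totals >= the knee barcode's total are retained, so the
    retained set is a prefix of the rank-sorted barcodes.  A degenerate
    curve (all positive totals equal) retains every positive barcode.

    Parameters
    ----------
    barcode_umi_totals
        Per-barcode UMI totals (array-like or pandas Series).

    Returns
    -------
    numpy.ndarray
        Boolean retention mask aligned with the input.
    """
    totals = np.asarray(barcode_umi_totals, dtype=float)
    if totals.ndim != 1:
        raise ValueError("expected a 1-D vector of totals")
    if np.any(totals < 0):
        raise ValueError("totals must be non-negative")
    pos = totals > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("all barcode totals are zero")
    if n_pos < min_barcodes:
        raise ValueError(
            f"need at least {min_barcodes} barcodes with positive totals, got {n_pos}"
        )
    sorted_totals = np.sort(totals[pos])[::-1]
    y = np.log10(sorted_totals)
    x = np.log10(np.arange(1, n_pos + 1))
    if y[0] == y[-1]:  # flat curve: no knee, keep everything positive
        return pos
    # perpendicular distance of each point to the endpoint chord
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * x - dx * y + dx * y[0] - dy * x[0]) / np.hypot(dx, dy)
    knee = int(np.argmax(dist))  # argmax returns the first (highest-total) tie
    threshold = sorted_totals[knee]
    mask = totals >= threshold
    logger.info(
        "knee calling retained %d/%d barcodes (threshold %g)",
        int(mask.sum()),
        len(totals),
        threshold,
    )
    return mask


def _to_csr(X) -> sparse.csr_matrix:
    if sparse.issparse(X):
        return X.tocsr()
    return sparse.csr_matrix(np.asarray(X))


def compute_qc(adata: AnnData, mito_regex: str = MITO_REGEX) -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame indexed by cell id with ``n_genes`` (genes with
    count > 0), ``n_umis`` (total counts) and ``mito_fraction`` (UMIs in
    genes matching ``mito_regex``, case-insensitive, over total UMIs;
    0 by convention for all-zero cells).
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    X = _to_csr(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_umis = np.asarray(X.sum(axis=1)).ravel()
    pattern = re.compile(mito_regex, re.IGNORECASE)
    mito_mask = np.array([bool(pattern.search(g)) for g in adata.var_names])
    mito_umis = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umis > 0, mito_umis / np.maximum(n_umis, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_umis": n_umis.astype(int),
            "mito_fraction": mito_fraction,
        },
        index=adata.obs_names.copy(),
    )


def filter_cells(
    adata: AnnData,
    qc: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> AnnData:
    """Apply the cell-level QC filters (strict-inequality removal).

    A cell survives iff ``min_genes <= n_genes <= max_genes`` and
    ``n_umis <= max_umis`` and ``mito_fraction <= max_mito_fraction``.
    """
    if adata.n_obs == 0:
        return adata.copy()
    if qc is None:
        qc = compute_qc(adata)
    if not qc.index.equals(adata.obs_names):
        raise ValueError("qc table is not aligned with the matrix")
    keep = (
        (qc["n_genes"] >= thresholds.min_genes)
        & (qc["n_genes"] <= thresholds.max_genes)
        & (qc["n_umis"] <= thresholds.max_umis)
        & (qc["mito_fraction"] <= thresholds.max_mito_fraction)
    ).to_numpy()
    logger.info("QC retained %d/%d cells", int(keep.sum()), adata.n_obs)
    return adata[keep].copy()


def lognormalize(adata: AnnData, scale: float = 10_000.0) -> AnnData:
    """Library-size normalization to ``scale`` counts per cell, then ln(1+x).

    value = ln(1 + count * scale / cell_total); all-zero cells stay zero.
    Raw counts are preserved in ``layers['counts']``.
    """
    X = _to_csr(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    factors = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = sparse.diags(factors) @ X
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.layers["counts"] = _to_csr(adata.X).copy()
    out.X = norm.tocsr()
    return out
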