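"""Expression-inferred relative copy-number profiles.

Non-malignant cells (immune + stromal) serve as the expression baseline.
Log-normalized expression is turned into per-gene deviations from the
baseline mean, smoothed along genomic gene order with a 101-gene window
that never crosses a chromosome boundary, median-centered per cell to 1,
and clipped at 1.5 standard deviations of the centered values.  The
result approximates relative copy state: values above 1 suggest gains,
below 1 losses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

logger = logging.getLogger(__name__)

# canonical chromosome order: 1..22, X, Y, then anything else (e.g. MT)
_CHROM_RANK = {f"chr{i}": i for i in range(1, 23)}
_CHROM_RANK.update({"chrX": 23, "chrY": 24})
_CHROM_RANK.update({str(i): i for i in range(1, 23)})
_CHROM_RANK.update({"X": 23, "Y": 24})


@dataclass(frozen=True)
class CNAParams:
    window_genes: int = 101
    min_cells_expressing: int = 20
    clip_sd: float = 1.5
    center_target: float = 1.0
    viz_cells_per_patient: int = 100

    def __post_init__(self) -> None:
        if self.window_genes < 1 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be odd and >= 1")
        if self.min_cells_expressing < 0:
            raise ValueError("min_cells_expressing must be >= 0")
        if self.clip_sd <= 0:
            raise ValueError("clip_sd must be > 0")


def chromosome_rank(chrom: str) -> tuple[int, str]:
    return (_CHROM_RANK.get(chrom, 1000), chrom)


def order_genes(adata: AnnData, gene_order: pd.DataFrame | None = None) -> AnnData:
    """Sort the gene axis by chromosome (1..22, X, Y, rest) then start.

    ``gene_order`` is a (gene, chromosome, start) table; if omitted the
    coordinates are taken from ``adata.var``.  Genes without coordinates
    are dropped with a warning.
    """
    if gene_order is not None:
        coords = gene_order.set_index("gene")[["chromosome", "start"]]
        present = adata.var_names.intersection(coords.index)
        if len(present) < adata.n_vars:
            warnings.warn(
                f"{adata.n_vars - len(present)} genes lack genomic coordinates; dropped"
            )
        adata = adata[:, present].copy()
        adata.var["chromosome"] = coords.loc[adata.var_names, "chromosome"].to_numpy()
        adata.var["start"] = coords.loc[adata.var_names, "start"].to_numpy()
    if "chromosome" not in adata.var or "start" not in adata.var:
        raise ValueError("gene coordinates missing; provide a gene_order table")
    key = sorted(
        range(adata.n_vars),
        key=lambda i: (
            chromosome_rank(str(adata.var["chromosome"].iloc[i])),
            adata.var["start"].iloc[i],
        ),
    )
    return adata[:, key].copy()


def filter_genes(adata: AnnData, params: CNAParams = CNAParams()) -> AnnData:
    """Drop genes expressed (count > 0) in fewer than ``min_cells_expressing`` cells."""
    X = adata.layers.get("counts", adata.X)
    if sparse.issparse(X):
        n_expressing = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_expressing = (np.asarray(X) > 0).sum(axis=0)
    keep = n_expressing >= params.min_cells_expressing
    if not keep.any():
        raise ValueError("all genes removed by the expression-prevalence filter")
    logger.info("gene filter retained %d/%d genes", int(keep.sum()), adata.n_vars)
    return adata[:, keep].copy()


def relative_expression(X, reference_mask) -> np.ndarray:
    """Per-gene deviation from the mean over reference cells.

    value(cell, gene) = X[cell, gene] - mean over reference cells of X[., gene].
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() == 0:
        raise ValueError("reference cell set is empty")
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    else:
        X = np.asarray(X, dtype=float)
    if reference_mask.shape[0] != X.shape[0]:
        raise ValueError("reference mask not aligned with matrix")
    baseline = X[reference_mask].mean(axis=0)
    return X - baseline[None, :]


def _running_mean_truncated(block: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along axis 1, truncated at block edges."""
    half = window // 2
    n = block.shape[1]
    cs = np.zeros((block.shape[0], n + 1))
    np.cumsum(block, axis=1, out=cs[:, 1:])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


def smooth_windows(
    rel: np.ndarray, chromosomes, params: CNAParams = CNAParams()
) -> np.ndarray:
    """Window-smooth deviations along gene order, per chromosome.

    Each value becomes the mean of the ``window_genes`` genes centered
    on it within its chromosome; windows are truncated (never mirrored)
    at chromosome ends and never span a boundary.  Genes of one
    chromosome must be contiguous in the input order.
    """
    chromosomes = np.asarray(chromosomes)
    if chromosomes.shape[0] != rel.shape[1]:
        raise ValueError("chromosome labels not aligned with gene axis")
    # detect block boundaries; require contiguity
    change = np.flatnonzero(chromosomes[1:] != chromosomes[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(chromosomes)]])
    seen: set[str] = set()
    out = np.empty_like(rel, dtype=float)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        chrom = str(chromosomes[lo])
        if chrom in seen:
            raise ValueError(f"genes of chromosome {chrom!r} are not contiguous")
        seen.add(chrom)
        out[:, lo:hi] = _running_mean_truncated(rel[:, lo:hi], params.window_genes)
    return out


def center_and_clip(
    smoothed: np.ndarray, params: CNAParams = CNAParams(), clip: bool = True
) -> np.ndarray:
    """Median-center each cell to ``center_target`` and clip extremes.

    The clip bounds are center_target +/- clip_sd * sigma, where sigma
    is the standard deviation of the whole centered matrix.  Zero
    variance returns the centered matrix unclipped.
    """
    if not np.all(np.isfinite(smoothed)):
        raise ValueError("smoothed matrix contains non-finite values")
    med = np.median(smoothed, axis=1, keepdims=True)
    centered = smoothed - med + params.center_target
    if not clip:
        return centered
    sigma = float(centered.std())
    if sigma == 0:
        return centered
    lo = params.center_target - params.clip_sd * sigma
    hi = params.center_target + params.clip_sd * sigma
    return np.clip(centered, lo, hi)


def infer_cna(
    adata_norm: AnnData,
    malignant_mask,
    params: CNAParams = CNAParams(),
    clip: bool = True,
) -> AnnData:
    """Full CNA inference on a log-normalized, genome-ordered matrix.

    Reference cells are all cells not flagged malignant.  Returns an
    AnnData of smoothed, centered (and by default clipped) relative
    values for every cell, with the input ``obs`` carried over and a
    ``malignant`` column set from ``malignant_mask``.
    """
    malignant_mask = np.asarray(malignant_mask, dtype=bool)
    if malignant_mask.shape[0] != adata_norm.n_obs:
        raise ValueError("malignant mask not aligned with matrix")
    adata = filter_genes(adata_norm, params)
    rel = relative_expression(adata.X, ~malignant_mask)
    smoothed = smooth_windows(rel, adata.var["chromosome"].to_numpy(), params)
    values = center_and_clip(smoothed, params, clip=clip)
    out = AnnData(X=values, obs=adata.obs.copy(), var=adata.var.copy())
    out.obs["malignant"] = malignant_mask
    return out


def subsample_for_viz(
    cna: AnnData, params: CNAParams = CNAParams(), seed: int = 0
) -> AnnData:
    """Per patient, keep at most ``viz_cells_per_patient`` malignant cells.

    Sampling is without replacement and deterministic given ``seed``.
    Non-malignant cells are dropped (the heatmap shows malignant cells).
    """
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    malignant = cna.obs["malignant"].to_numpy()
    patients = cna.obs["patient"].to_numpy()
    for patient in pd.unique(patients):
        rows = np.flatnonzero((patients == patient) & malignant)
        if len(rows) > params.viz_cells_per_patient:
            rows = rng.choice(rows, size=params.viz_cells_per_patient, replace=False)
            rows = np.sort(rows)
        keep.extend(rows.tolist())
    return cna[np.array(sorted(keep), dtype=int)].copy()
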