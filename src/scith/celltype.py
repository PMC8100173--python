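"""Marker-score cell typing, cancer-cluster identification and LUAD/LUSC calls.

Clusters (from any external clustering, or ground-truth labels in
simulation) are scored per cell type as the mean, over the type's
marker genes, of the gene's z-scored expression averaged over the
cluster's cells; each cluster is assigned its highest-scoring type.
Cancer clusters are EPCAM-positive clusters that score low on normal
lung epithelial programs.  Patients are classified LUAD/LUSC from the
fraction of malignant cells expressing the respective
immunohistochemistry marker panels, with NSCLC as the unclassified
residual when both scores fall below 0.05.
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

# Canonical marker panels for the major cell types of an NSCLC biopsy.
# "FOLR1" is the folate receptor (alveolar); "DSG3" the squamous
# desmoglein -- both are configurable interpretations of ambiguous
# shorthand marker names.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "Endothelial": ("CLDN5", "VWF", "PECAM1"),
    "Epithelial": ("CAPS", "SNTN"),
    "Alveolar": ("CLDN18", "AQP4", "FOLR1"),
    "Fibroblast": ("COL1A1", "COL1A2", "DCN"),
    "T": ("CD2", "CD3D", "CD3E", "CD3G"),
    "B": ("CD79A", "CD79B"),
    "Myeloid": ("CD14", "LYZ"),
    "Neutrophil": ("CSF3R", "S100A8", "S100A9"),
    "FDC": ("FDCSP",),
    "Mast": ("GATA2", "TPSAB1", "TPSB2"),
}

CANCER_MARKER = "EPCAM"
NORMAL_EPITHELIAL_TYPES = ("Epithelial", "Alveolar")
LUAD_MARKERS = ("NAPSA", "NKX2-1")  # TTF-1 maps to gene symbol NKX2-1
LUSC_MARKERS = ("KRT5", "DSG3", "TP63")


@dataclass
class ClusterScores:
    """Per-cluster marker scores and the winning type per cluster."""

    scores: pd.DataFrame  # clusters x cell types
    winners: pd.Series  # cluster -> winning type


@dataclass(frozen=True)
class SubtypeCall:
    patient: str
    luad_score: float
    lusc_score: float
    label: str


def _dense_columns(X, cols: np.ndarray) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X[:, cols].todense(), dtype=float)
    return np.asarray(X, dtype=float)[:, cols]


def score_clusters(
    adata_norm: AnnData,
    clusters,
    markers: dict[str, tuple[str, ...]] | None = None,
) -> ClusterScores:
    """Score every cluster against every marker panel.

    score(cluster, type) = mean over the type's resolvable markers of
    the z-scored (across all cells) expression averaged over the
    cluster's cells.  Missing marker genes are warned about and
    skipped; a type with no resolvable marker is excluded with a
    warning.  Winners are argmax per cluster, ties broken by marker-set
    definition order with a warning.
    """
    if markers is None:
        markers = DEFAULT_MARKERS
    clusters = np.asarray(clusters)
    if clusters.shape[0] != adata_norm.n_obs:
        raise ValueError("cluster labels not aligned with matrix")
    cluster_ids = pd.unique(clusters)

    resolvable: dict[str, np.ndarray] = {}
    for ctype, genes in markers.items():
        idx = adata_norm.var_names.get_indexer(genes)
        missing = [g for g, i in zip(genes, idx) if i < 0]
        if missing:
            warnings.warn(f"markers not in matrix for {ctype!r}: {missing}")
        idx = idx[idx >= 0]
        if len(idx) == 0:
            warnings.warn(f"cell type {ctype!r} has no resolvable markers; excluded")
            continue
        resolvable[ctype] = idx

    if not resolvable:
        raise ValueError("no marker panel has resolvable genes")

    all_cols = np.unique(np.concatenate(list(resolvable.values())))
    col_pos = {c: i for i, c in enumerate(all_cols)}
    M = _dense_columns(adata_norm.X, all_cols)
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (M - mean) / sd_safe
    Z[:, sd == 0] = 0.0  # constant genes carry no information

    rows = {}
    for cid in cluster_ids:
        in_cluster = clusters == cid
        cluster_z = Z[in_cluster].mean(axis=0)
        rows[cid] = {
            ctype: float(np.mean([cluster_z[col_pos[c]] for c in cols]))
            for ctype, cols in resolvable.items()
        }
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores = scores[[t for t in resolvable]]  # definition order

    winners = {}
    for cid in scores.index:
        row = scores.loc[cid]
        best = row.max()
        tied = [t for t in scores.columns if row[t] == best]
        if len(tied) > 1:
            warnings.warn(f"cluster {cid!r}: tie between {tied}; first in definition order wins")
        winners[cid] = tied[0]
    return ClusterScores(scores=scores, winners=pd.Series(winners, name="winner"))


def identify_cancer_clusters(
    cluster_scores: ClusterScores,
    adata: AnnData,
    clusters,
    epcam_gene: str = CANCER_MARKER,
    normal_types: tuple[str, ...] = NORMAL_EPITHELIAL_TYPES,
    min_epcam_fraction: float = 0.3,
    max_normal_score: float = 0.5,
) -> set:
    """Flag clusters positive for EPCAM and negative for normal epithelium.

    A cluster is malignant iff its fraction of EPCAM-positive
    (count > 0) cells is >= ``min_epcam_fraction`` and all its
    ``normal_types`` marker scores are below ``max_normal_score``.
    """
    clusters = np.asarray(clusters)
    if epcam_gene not in adata.var_names:
        warnings.warn(f"{epcam_gene!r} not in matrix; no cancer clusters flagged")
        return set()
    X = adata.layers.get("counts", adata.X)
    col = adata.var_names.get_loc(epcam_gene)
    if sparse.issparse(X):
        positive = np.asarray((X[:, [col]] > 0).todense()).ravel()
    else:
        positive = np.asarray(X)[:, col] > 0
    flagged = set()
    for cid in cluster_scores.scores.index:
        in_cluster = clusters == cid
        if not in_cluster.any():
            continue
        epcam_frac = float(positive[in_cluster].mean())
        normal_ok = all(
            cluster_scores.scores.loc[cid, t] < max_normal_score
            for t in normal_types
            if t in cluster_scores.scores.columns
        )
        if epcam_frac >= min_epcam_fraction and normal_ok:
            flagged.add(cid)
    logger.info("flagged %d cancer clusters", len(flagged))
    return flagged


def _positive_fraction(X, var_names: pd.Index, genes: tuple[str, ...]) -> list[float]:
    fracs = []
    for g in genes:
        if g not in var_names:
            warnings.warn(f"subtype marker {g!r} not in matrix; fraction treated as 0")
            fracs.append(0.0)
            continue
        col = var_names.get_loc(g)
        if sparse.issparse(X):
            positive = np.asarray((X[:, [col]] > 0).todense()).ravel()
        else:
            positive = np.asarray(X)[:, col] > 0
        fracs.append(float(positive.mean()))
    return fracs


def subtype_scores(
    adata_malignant: AnnData,
    patient: str,
    luad_markers: tuple[str, ...] = LUAD_MARKERS,
    lusc_markers: tuple[str, ...] = LUSC_MARKERS,
    nsclc_cutoff: float = 0.05,
) -> SubtypeCall:
    """LUAD/LUSC classification of one patient's malignant cells.

    Each subtype score is the mean, over its marker panel, of the
    fraction of malignant cells expressing the marker (count > 0).
    Both scores below ``nsclc_cutoff`` yields the residual label NSCLC;
    otherwise the higher-scoring subtype wins (ties -> LUAD, the first
    panel in definition order, with a warning).
    """
    if adata_malignant.n_obs == 0:
        raise ValueError(f"patient {patient!r} has no malignant cells")
    X = adata_malignant.layers.get("counts", adata_malignant.X)
    luad = float(np.mean(_positive_fraction(X, adata_malignant.var_names, luad_markers)))
    lusc = float(np.mean(_positive_fraction(X, adata_malignant.var_names, lusc_markers)))
    if luad < nsclc_cutoff and lusc < nsclc_cutoff:
        label = "NSCLC"
    elif luad == lusc:
        warnings.warn(f"patient {patient!r}: tied subtype scores; LUAD assigned")
        label = "LUAD"
    else:
        label = "LUAD" if luad > lusc else "LUSC"
    return SubtypeCall(patient=patient, luad_score=luad, lusc_score=lusc, label=label)
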