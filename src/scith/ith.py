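"""Intratumor heterogeneity scores and the comparisons built on them.

For each patient, all pairwise Pearson correlation coefficients among
the malignant cells' profiles are computed; the heterogeneity score is
the interquartile range (IQR) of that distribution.  ITH_CNA uses the
inferred relative copy-number matrix, ITH_GEX the log-normalized
expression matrix.  A homogeneous tumor (all malignant cells alike)
yields tightly clustered correlations and a score near 0; divergent
clones spread the correlations and raise the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse, stats

DEFAULT_GROUP_PAIRS = (("LUSCn", "LUADm"), ("LUSCn", "LUADn"), ("LUADm", "LUADn"))


def pairwise_pearson(profiles) -> np.ndarray:
    """Pearson correlation for every unordered pair of rows.

    Rows with zero variance have undefined correlations and are excluded
    with a warning reporting how many were dropped.
    """
    if sparse.issparse(profiles):
        profiles = np.asarray(profiles.todense())
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("insufficient cells: need at least 3 profiles")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"excluded {int(constant.sum())} constant profiles")
        X = X[~constant]
    if X.shape[0] < 2:
        return np.empty(0)
    corr = np.corrcoef(X)
    iu = np.triu_indices(X.shape[0], k=1)
    return np.clip(corr[iu], -1.0, 1.0)


def ith_score(correlations) -> float:
    """Interquartile range (Q3 - Q1, linear interpolation) of the input."""
    r = np.asarray(correlations, dtype=float)
    if r.size == 0:
        raise ValueError("empty correlation vector")
    q1, q3 = np.percentile(r, [25, 75])
    return float(q3 - q1)


@dataclass
class ITHResult:
    patient: str
    ith_cna: float
    ith_gex: float
    n_malignant_cells: int
    defined: bool = True
    correlations_cna: np.ndarray | None = field(default=None, repr=False)
    correlations_gex: np.ndarray | None = field(default=None, repr=False)


def compute_ith(
    patient: str,
    cna_profiles,
    gex_profiles,
    keep_correlations: bool = False,
) -> ITHResult:
    """ITH_CNA and ITH_GEX for one patient's malignant cells.

    Both inputs are cells x features matrices restricted to the
    patient's malignant cells.  With fewer than 3 cells the scores are
    undefined (NaN, ``defined=False``).
    """
    n = np.asarray(cna_profiles).shape[0] if not sparse.issparse(cna_profiles) else cna_profiles.shape[0]
    if n < 3:
        return ITHResult(patient, float("nan"), float("nan"), n, defined=False)
    r_cna = pairwise_pearson(cna_profiles)
    r_gex = pairwise_pearson(gex_profiles)
    return ITHResult(
        patient=patient,
        ith_cna=ith_score(r_cna),
        ith_gex=ith_score(r_gex),
        n_malignant_cells=n,
        correlations_cna=r_cna if keep_correlations else None,
        correlations_gex=r_gex if keep_correlations else None,
    )


def results_table(results: list[ITHResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [r.patient for r in results],
            "ith_cna": [r.ith_cna for r in results],
            "ith_gex": [r.ith_gex for r in results],
            "n_malignant_cells": [r.n_malignant_cells for r in results],
            "defined": [r.defined for r in results],
        }
    ).set_index("patient")


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U).

    Exact null distribution for combined n <= 25 without ties, normal
    approximation with tie correction otherwise.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    ith: pd.DataFrame,
    groups: pd.Series | dict,
    scores: tuple[str, ...] = ("ith_cna", "ith_gex"),
    pairs: tuple[tuple[str, str], ...] = DEFAULT_GROUP_PAIRS,
) -> pd.DataFrame:
    """Two-sided rank-sum tests of ITH scores between patient groups.

    ``ith`` is the table from :func:`results_table`; ``groups`` maps
    patient id to group label.  Group pairs with fewer than 2 patients
    in either group are skipped with a warning.
    """
    groups = pd.Series(groups)
    rows = []
    for score in scores:
        values = ith.loc[ith["defined"].astype(bool), score]
        for g1, g2 in pairs:
            x = values[groups.reindex(values.index) == g1].dropna().to_numpy()
            y = values[groups.reindex(values.index) == g2].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2:
                warnings.warn(f"skipping {g1} vs {g2} for {score}: group with < 2 patients")
                continue
            stat, p = _ranksum(x, y)
            rows.append(
                {
                    "score": score,
                    "group1": g1,
                    "group2": g2,
                    "n1": len(x),
                    "n2": len(y),
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def correlate_ith_composition(
    ith: pd.DataFrame,
    composition: pd.DataFrame,
    score: str = "ith_gex",
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Pearson correlation of an ITH score with cell-type proportions.

    ``composition`` is patients x cell types and must row-sum to 1.
    p-values come from the two-sided t distribution with n - 2 df
    (scipy's pearsonr); cell types with p < alpha are flagged
    significant.
    """
    sums = composition.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError("composition rows must sum to 1")
    common = ith.index.intersection(composition.index)
    defined = ith.loc[common, "defined"].astype(bool)
    common = common[defined.to_numpy()]
    if len(common) < 4:
        raise ValueError("need at least 4 patients with defined ITH")
    x = ith.loc[common, score].to_numpy()
    rows = []
    for cell_type in composition.columns:
        y = composition.loc[common, cell_type].to_numpy()
        if np.std(y) == 0 or np.std(x) == 0:
            r, p = float("nan"), float("nan")
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"cell_type": cell_type, "r": r, "p_value": p, "significant": bool(p < alpha) if np.isfinite(p) else False}
        )
    return pd.DataFrame(rows).set_index("cell_type")
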