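"""Ligand-receptor interaction testing and interaction networks.

Per patient, each (ligand-receptor pair, sender type, receiver type)
triple is scored as the mean of the ligand's mean expression in the
sender type and the receptor's mean expression in the receiver type.
Significance comes from permuting cell-type labels across cells:
p = (1 + #{null >= observed}) / (N + 1).  Pairs whose ligand or
receptor is expressed in less than 10% of the respective type are
non-specific by construction and get p = 1.  A per-patient specificity
rank (fraction of type-pairs in which the pair is significant) filters
promiscuous pairs; triples retained in more than five patients form the
cohort-level interaction set from which the cell-type network and the
gene-only network (four largest connected components) are built.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

# Small curated ligand-receptor universe for tests and the bundled demo
# pipeline; real analyses should supply a full database TSV.
DEFAULT_LR_PAIRS: tuple[tuple[str, str], ...] = (
    ("CXCL1", "CXCR1"), ("CXCL1", "CXCR2"),
    ("CXCL2", "CXCR1"), ("CXCL2", "CXCR2"),
    ("CXCL3", "CXCR1"), ("CXCL3", "CXCR2"),
    ("CXCL8", "CXCR1"), ("CXCL8", "CXCR2"),
    ("CXCL5", "CXCR2"),
    ("CXCL9", "CXCR3"), ("CXCL10", "CXCR3"), ("CXCL11", "CXCR3"),
    ("CXCL12", "CXCR4"),
    ("CCL2", "CCR2"), ("CCL5", "CCR5"), ("CCL13", "CCR2"),
    ("VEGFA", "FLT1"), ("VEGFA", "KDR"), ("VEGFB", "FLT1"),
    ("PDGFA", "PDGFRA"), ("PDGFB", "PDGFRB"), ("PDGFC", "PDGFRA"),
    ("FGF1", "FGFR1"), ("FGF2", "FGFR1"), ("FGF7", "FGFR2"),
    ("EGF", "EGFR"), ("TGFA", "EGFR"), ("HBEGF", "EGFR"),
    ("TGFB1", "TGFBR1"), ("TNF", "TNFRSF1A"),
    ("JAG1", "NOTCH1"), ("DLL1", "NOTCH1"), ("WNT5A", "FZD1"),
    ("TIGIT", "PVR"), ("CD226", "PVR"), ("CD96", "PVR"),
    ("CD274", "PDCD1"), ("PDCD1LG2", "PDCD1"),
    ("CTLA4", "CD80"), ("CTLA4", "CD86"), ("CD28", "CD80"), ("CD28", "CD86"),
    ("HAVCR2", "LGALS9"),
    ("IL6", "IL6R"), ("IL1B", "IL1R1"), ("CSF1", "CSF1R"),
)


def default_lr_database() -> pd.DataFrame:
    """The bundled ligand-receptor pair table (ligand, receptor, pair_id)."""
    return pd.DataFrame(
        [
            {"ligand": l, "receptor": r, "pair_id": f"{l}_{r}"}
            for l, r in DEFAULT_LR_PAIRS
        ]
    )


def _validate_db(db: pd.DataFrame) -> pd.DataFrame:
    db = db.copy()
    if "pair_id" not in db.columns:
        db["pair_id"] = db["ligand"] + "_" + db["receptor"]
    if db["pair_id"].duplicated().any():
        raise ValueError("pair ids must be unique")
    if (db["ligand"].str.len() == 0).any() or (db["receptor"].str.len() == 0).any():
        raise ValueError("ligand/receptor gene names must be nonempty")
    return db


def permutation_test(
    adata_norm,
    type_labels,
    db: pd.DataFrame | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_expression_fraction: float = 0.10,
) -> pd.DataFrame:
    """Label-permutation test for every (pair, sender, receiver) triple.

    Parameters
    ----------
    adata_norm
        Log-normalized AnnData (or anything with ``.X`` and
        ``.var_names``).
    type_labels
        Cell-type label per cell.
    db
        Ligand-receptor table with columns ligand/receptor (and
        optionally pair_id); defaults to the bundled database.  Pairs
        whose genes are absent from the matrix are skipped with a
        warning.
    n_permutations
        Size N of the permutation null; p-values live in [1/(N+1), 1].

    Returns
    -------
    DataFrame with one row per (pair, sender, receiver): the statistic,
    the permutation p-value and a significance flag at ``alpha``.
    """
    if db is None:
        db = default_lr_database()
    db = _validate_db(db)
    labels = np.asarray(type_labels)
    X = adata_norm.X
    var_names = adata_norm.var_names
    if labels.shape[0] != X.shape[0]:
        raise ValueError("type labels not aligned with matrix")

    types = [t for t in pd.unique(labels) if t != ""]
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    counts = np.array([(labels == t).sum() for t in types])
    keep_types = [t for t, c in zip(types, counts) if c > 0]
    if len(keep_types) < len(types):
        warnings.warn("skipped cell types with 0 cells")
    types = keep_types
    T = len(types)

    li = var_names.get_indexer(db["ligand"])
    ri = var_names.get_indexer(db["receptor"])
    ok = (li >= 0) & (ri >= 0)
    if not ok.all():
        missing = db.loc[~ok, "pair_id"].tolist()
        warnings.warn(f"skipping pairs with genes absent from matrix: {missing}")
    db = db.loc[ok].reset_index(drop=True)
    li, ri = li[ok], ri[ok]
    if len(db) == 0:
        raise ValueError("no ligand-receptor pair resolvable against the matrix")

    used = np.unique(np.concatenate([li, ri]))
    pos = {g: i for i, g in enumerate(used)}
    lcol = np.array([pos[g] for g in li])
    rcol = np.array([pos[g] for g in ri])
    if sparse.issparse(X):
        Xu = np.asarray(X[:, used].todense(), dtype=float)
    else:
        Xu = np.asarray(X, dtype=float)[:, used]
    n_cells = Xu.shape[0]

    # type-indicator averaging operator (T x cells)
    A = np.zeros((T, n_cells))
    for i, t in enumerate(types):
        rows = labels == t
        A[i, rows] = 1.0 / rows.sum()

    M = A @ Xu  # T x genes mean expression
    frac = A @ (Xu > 0)  # T x genes expressing fraction

    ML, MR = M[:, lcol], M[:, rcol]  # T x P
    obs = 0.5 * (ML[:, None, :] + MR[None, :, :])  # sender x receiver x pair

    rng = np.random.default_rng(seed)
    count_ge = np.zeros_like(obs, dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n_cells)
        Mp = A @ Xu[perm]
        null = 0.5 * (Mp[:, lcol][:, None, :] + Mp[:, rcol][None, :, :])
        count_ge += null >= obs
    pvals = (1.0 + count_ge) / (n_permutations + 1.0)

    # expression floor: non-specific pairs get p = 1
    low_l = frac[:, lcol] < min_expression_fraction  # sender x pair
    low_r = frac[:, rcol] < min_expression_fraction  # receiver x pair
    floor = low_l[:, None, :] | low_r[None, :, :]
    pvals = np.where(floor, 1.0, pvals)

    s_idx, r_idx, p_idx = np.meshgrid(
        np.arange(T), np.arange(T), np.arange(len(db)), indexing="ij"
    )
    out = pd.DataFrame(
        {
            "pair_id": db["pair_id"].to_numpy()[p_idx.ravel()],
            "ligand": db["ligand"].to_numpy()[p_idx.ravel()],
            "receptor": db["receptor"].to_numpy()[p_idx.ravel()],
            "sender": np.array(types)[s_idx.ravel()],
            "receiver": np.array(types)[r_idx.ravel()],
            "statistic": obs.ravel(),
            "p_value": pvals.ravel(),
        }
    )
    out["significant"] = out["p_value"] < alpha
    return out


def compute_rank(tests: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair specificity rank for one patient's tests.

    rank(pair) = #{(sender, receiver) with p < alpha} / #{type-pairs
    evaluated}.  Returns the input with a ``rank`` column added.
    """
    tests = tests.copy()
    sig = tests["p_value"] < alpha
    grouped = sig.groupby(tests["pair_id"])
    rank = grouped.sum() / grouped.count()
    tests["rank"] = tests["pair_id"].map(rank)
    return tests


def retained_tests(
    tests: pd.DataFrame, alpha: float = 0.05, max_rank: float = 0.1
) -> pd.DataFrame:
    """Significant, specific triples for one patient (p < alpha, rank <= max_rank)."""
    if "rank" not in tests.columns:
        tests = compute_rank(tests, alpha=alpha)
    keep = (tests["p_value"] < alpha) & (tests["rank"] <= max_rank)
    return tests.loc[keep].reset_index(drop=True)


def aggregate_patients(
    tests_by_patient: dict[str, pd.DataFrame],
    min_patients: int = 5,
    alpha: float = 0.05,
    max_rank: float = 0.1,
    groups: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Cohort-level retained interactions.

    A (pair, sender, receiver) triple is retained iff it passes the
    per-patient significance and rank filters in strictly more than
    ``min_patients`` patients.  With ``groups`` given (patient ->
    group), per-group patient fractions are annotated for dot-plot style
    reporting.
    """
    per_patient = {
        p: retained_tests(t, alpha=alpha, max_rank=max_rank)
        for p, t in tests_by_patient.items()
    }
    rows: dict[tuple, set] = {}
    for patient, t in per_patient.items():
        for key in zip(t["pair_id"], t["ligand"], t["receptor"], t["sender"], t["receiver"]):
            rows.setdefault(key, set()).add(patient)
    records = []
    groups = pd.Series(groups) if groups is not None else None
    for (pair_id, ligand, receptor, sender, receiver), patients in rows.items():
        if len(patients) <= min_patients:
            continue
        rec = {
            "pair_id": pair_id,
            "ligand": ligand,
            "receptor": receptor,
            "sender": sender,
            "receiver": receiver,
            "n_patients": len(patients),
        }
        if groups is not None:
            for g in pd.unique(groups):
                members = set(groups.index[groups == g])
                rec[f"frac_{g}"] = (
                    len(patients & members) / len(members) if members else 0.0
                )
        records.append(rec)
    cols = ["pair_id", "ligand", "receptor", "sender", "receiver", "n_patients"]
    if groups is not None:
        cols += [f"frac_{g}" for g in pd.unique(groups)]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(records).sort_values(
        ["n_patients", "pair_id"], ascending=[False, True]
    ).reset_index(drop=True)


def build_celltype_network(
    retained: pd.DataFrame, min_interactions: int = 500
) -> nx.Graph:
    """Undirected cell-type network weighted by retained interaction counts.

    Directions are summed into one undirected edge weight.  Cell types
    whose total retained interaction count falls below
    ``min_interactions`` are removed (the default matches a large
    cohort; scale it down for small synthetic ones).
    """
    if len(retained) == 0:
        warnings.warn("empty retained interaction set; empty network")
        return nx.Graph()
    weights: dict[frozenset, int] = {}
    totals: dict[str, int] = {}
    for sender, receiver in zip(retained["sender"], retained["receiver"]):
        key = frozenset((sender, receiver))
        weights[key] = weights.get(key, 0) + 1
        for t in {sender, receiver}:
            totals[t] = totals.get(t, 0) + 1
    keep = {t for t, n in totals.items() if n >= min_interactions}
    G = nx.Graph()
    G.add_nodes_from(sorted(keep))
    for key, w in weights.items():
        nodes = sorted(key)
        a, b = (nodes[0], nodes[0]) if len(nodes) == 1 else nodes
        if a in keep and b in keep:
            G.add_edge(a, b, weight=w)
    if G.number_of_nodes() == 0:
        warnings.warn("all cell types fell below the interaction threshold")
    return G


def build_gene_network(
    retained: pd.DataFrame,
    type_expression: pd.DataFrame | None = None,
    expression_floor: float = 0.1,
    n_components: int = 4,
) -> list[nx.Graph]:
    """Gene-only interaction network as its largest connected components.

    A master graph joins cell-type nodes to the genes they express above
    ``expression_floor`` (mean expression, from ``type_expression``:
    types x genes) and genes to each other for every retained
    ligand-receptor pair.  Cell-type nodes are then deleted and the
    ``n_components`` largest components by node count are returned (ties
    broken by edge count, then by lexicographically smallest member).
    Fewer components than requested returns them all with a note.
    """
    if len(retained) == 0:
        warnings.warn("empty retained interaction set; empty network")
        return []
    genes = sorted(set(retained["ligand"]) | set(retained["receptor"]))
    master = nx.Graph()
    master.add_nodes_from(genes, kind="gene")
    if type_expression is not None:
        for t in type_expression.index:
            master.add_node(("celltype", t), kind="celltype")
            for g in genes:
                if g in type_expression.columns and type_expression.loc[t, g] >= expression_floor:
                    master.add_edge(("celltype", t), g)
    for ligand, receptor in zip(retained["ligand"], retained["receptor"]):
        master.add_edge(ligand, receptor, kind="lr")
    master.remove_nodes_from(
        [n for n, d in master.nodes(data=True) if d.get("kind") == "celltype"]
    )
    comps = [master.subgraph(c).copy() for c in nx.connected_components(master)]
    comps.sort(
        key=lambda g: (-g.number_of_nodes(), -g.number_of_edges(), min(g.nodes))
    )
    if len(comps) < n_components:
        logger.info("only %d connected components available", len(comps))
    return comps[:n_components]
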