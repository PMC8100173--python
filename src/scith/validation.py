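"""Reproduction experiments on synthetic cohorts with planted truth.

Each function here regenerates its inputs from a seed, runs the package
end to end on them, and returns the measured quantity: heterogeneity
directionality between clone-count groups, copy-number recovery and
null calibration, interaction-test calibration and planted-signal
recovery, subtype-label recovery, and exact QC boundary behavior.
Both the test suite and ``scripts/acceptance.py`` are thin wrappers
around these runners.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import interactions as ia
from .cna import CNAParams, infer_cna
from .ith import ith_score, pairwise_pearson
from .celltype import subtype_scores
from .qc import lognormalize
from .simulate import (
    CellTypeProfile,
    CNASegment,
    LRSignal,
    SimulationConfig,
    generate_cohort,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _neutral_profiles() -> dict[str, CellTypeProfile]:
    return {
        "Cancer": CellTypeProfile(markers=(), malignant=True),
        "Stromal": CellTypeProfile(markers=()),
    }


def _patient_ith_cna(adata, params: CNAParams) -> float:
    norm = lognormalize(adata)
    malignant = adata.obs["malignant"].to_numpy()
    cna = infer_cna(norm, malignant, params)
    mal_rows = np.flatnonzero(cna.obs["malignant"].to_numpy())
    return ith_score(pairwise_pearson(cna.X[mal_rows]))


def ith_directionality_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    n_two_clone: int = 16,
    n_one_clone: int = 12,
    n_malignant: int = 300,
    n_reference: int = 150,
    gain_fold: float = 2.0,
    loss_fold: float = 0.5,
) -> pd.DataFrame:
    """Two-clone vs one-clone cohorts: does ITH_CNA separate them?

    Every patient's clone 0 carries a 150-gene gain (``gain_fold``) on
    chr1; two-clone patients additionally split their malignant cells
    with a divergent clone carrying a 150-gene loss (``loss_fold``) on
    chr2.  Per replicate the medians of both groups and the two-sided
    rank-sum p-value are recorded.
    """
    segments = (
        CNASegment("chr1", 30, 150, gain_fold, clone=0),
        CNASegment("chr2", 30, 150, loss_fold, clone=1),
    )
    params = CNAParams()
    rows = []
    for rep_seed in _child_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_patients=n_two_clone + n_one_clone,
            cell_type_profiles=_neutral_profiles(),
            n_cells_per_type={"Cancer": n_malignant, "Stromal": n_reference},
            patient_clones=[2] * n_two_clone + [1] * n_one_clone,
            cna_segments=segments,
            lr_signals=(),
            marker_baseline_mean=None,
            seed=rep_seed,
        )
        adatas, _, _ = generate_cohort(cfg)
        scores = np.array([_patient_ith_cna(a, params) for a in adatas])
        two, one = scores[:n_two_clone], scores[n_two_clone:]
        res = stats.mannwhitneyu(two, one, alternative="two-sided")
        rows.append(
            {
                "median_two_clone": float(np.median(two)),
                "median_one_clone": float(np.median(one)),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def _rank_auroc(positive: np.ndarray, negative: np.ndarray) -> float:
    """AUROC via the rank-sum identity AUC = U / (n_pos * n_neg)."""
    values = np.concatenate([positive, negative])
    ranks = stats.rankdata(values)
    n_pos, n_neg = len(positive), len(negative)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def cna_recovery_experiment(
    seed: int = 0,
    n_malignant: int = 500,
    n_reference: int = 500,
    segment_length: int = 150,
    fold: float = 2.0,
) -> dict:
    """Planted-gain recovery: inside-vs-outside AUROC of per-gene means.

    One clone carries a contiguous ``fold`` gain over ``segment_length``
    genes on chr1; the per-gene mean smoothed signal of malignant cells
    classifies inside vs outside genes.
    """
    seg = CNASegment("chr1", 30, segment_length, fold, clone=0)
    cfg = SimulationConfig(
        n_patients=1,
        cell_type_profiles=_neutral_profiles(),
        n_cells_per_type={"Cancer": n_malignant, "Stromal": n_reference},
        cna_segments=(seg,),
        lr_signals=(),
        marker_baseline_mean=None,
        seed=seed,
    )
    adatas, _, gene_order = generate_cohort(cfg)
    adata = adatas[0]
    norm = lognormalize(adata)
    cna = infer_cna(norm, adata.obs["malignant"].to_numpy(), CNAParams())

    pos_in_chrom = gene_order.groupby("chromosome", sort=False).cumcount()
    inside = set(
        gene_order.loc[
            (gene_order["chromosome"] == seg.chromosome)
            & (pos_in_chrom >= seg.start)
            & (pos_in_chrom < seg.stop),
            "gene",
        ]
    )
    mal = cna.obs["malignant"].to_numpy()
    gene_means = np.asarray(cna.X[mal].mean(axis=0)).ravel()
    is_inside = np.array([g in inside for g in cna.var_names])
    return {
        "auroc": _rank_auroc(gene_means[is_inside], gene_means[~is_inside]),
        "inside_mean": float(gene_means[is_inside].mean()),
        "outside_mean": float(gene_means[~is_inside].mean()),
        "n_inside": int(is_inside.sum()),
        "n_outside": int((~is_inside).sum()),
    }


def cna_null_experiment(
    n_seeds: int = 20, seed: int = 0, n_cells: int = 200, subsample: int = 2000
) -> list[float]:
    """Copy-neutral simulation: KS p-values, malignant vs reference values.

    Smoothed values within a cell are strongly window-correlated, so a
    seeded subsample of ``subsample`` values per group keeps the KS test
    honestly calibrated with respect to its nominal sample size.
    """
    pvals = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(
            n_patients=1,
            cell_type_profiles=_neutral_profiles(),
            n_cells_per_type={"Cancer": n_cells, "Stromal": n_cells},
            cna_segments=(),
            lr_signals=(),
            marker_baseline_mean=None,
            seed=s,
        )
        adatas, _, _ = generate_cohort(cfg)
        adata = adatas[0]
        norm = lognormalize(adata)
        cna = infer_cna(norm, adata.obs["malignant"].to_numpy(), CNAParams())
        mal = cna.obs["malignant"].to_numpy()
        rng = np.random.default_rng(s)
        x = rng.choice(cna.X[mal].ravel(), size=subsample, replace=False)
        y = rng.choice(cna.X[~mal].ravel(), size=subsample, replace=False)
        pvals.append(float(stats.ks_2samp(x, y).pvalue))
    return pvals


def _four_type_config(seed: int, cells_per_type: int = 250, **overrides) -> SimulationConfig:
    profiles = {t: CellTypeProfile(markers=()) for t in "ABCD"}
    overrides.setdefault("lr_signals", ())
    return SimulationConfig(
        n_patients=1,
        genes_per_chromosome={"chr1": 200, "chr2": 200},
        cell_type_profiles=profiles,
        n_cells_per_type={t: cells_per_type for t in "ABCD"},
        mito_gene_count=0,
        mito_mass_fraction=0.0,
        seed=seed,
        **overrides,
    )


def interaction_null_calibration(
    n_seeds: int = 10,
    seed: int = 0,
    n_permutations: int = 1000,
    n_pairs: int = 80,
    alpha: float = 0.05,
) -> dict:
    """Global-null type-I error of the permutation test at ``alpha``.

    Cell types carry no signal; ligand-receptor pairs are drawn from
    well-expressed genes so the specificity floor never bites and every
    test exercises the permutation null.
    """
    n_sig = 0
    n_tests = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = _four_type_config(s)
        adatas, _, _ = generate_cohort(cfg)
        norm = lognormalize(adatas[0])
        frac = np.asarray((norm.X > 0).mean(axis=0)).ravel()
        eligible = np.array(norm.var_names)[frac >= 0.3]
        rng = np.random.default_rng(s)
        genes = rng.choice(eligible, size=2 * n_pairs, replace=False)
        db = pd.DataFrame(
            {"ligand": genes[:n_pairs], "receptor": genes[n_pairs:]}
        )
        tests = ia.permutation_test(
            norm,
            norm.obs["cell_type"].to_numpy(),
            db=db,
            n_permutations=n_permutations,
            seed=s,
            alpha=alpha,
        )
        n_sig += int((tests["p_value"] < alpha).sum())
        n_tests += len(tests)
    return {"type_i_error": n_sig / n_tests, "n_tests": n_tests}


def interaction_planted_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n_permutations: int = 1000,
    effect: float = 10.0,
    n_decoys: int = 30,
) -> pd.DataFrame:
    """Planted (ligand, receptor, sender, receiver) signal recovery.

    The planted genes are lowly expressed at baseline (cell-type
    specific, like real ligand-receptor partners) and strongly
    upregulated in the sender/receiver types; recovery means the minimal
    attainable p-value 1/(N+1) together with specificity rank <= 0.1.
    """
    signal = LRSignal("LIGX", "RECX", "A", "B", effect=effect)
    rows = []
    for s in _child_seeds(seed, n_seeds):
        cfg = _four_type_config(s, lr_signals=(signal,))
        adatas, _, _ = generate_cohort(cfg)
        norm = lognormalize(adatas[0])
        frac = np.asarray((norm.X > 0).mean(axis=0)).ravel()
        eligible = [
            g for g, f in zip(norm.var_names, frac)
            if f >= 0.3 and g not in ("LIGX", "RECX")
        ]
        rng = np.random.default_rng(s)
        genes = rng.choice(eligible, size=2 * n_decoys, replace=False)
        db = pd.DataFrame(
            {
                "ligand": ["LIGX", *genes[:n_decoys]],
                "receptor": ["RECX", *genes[n_decoys:]],
            }
        )
        tests = ia.compute_rank(
            ia.permutation_test(
                norm,
                norm.obs["cell_type"].to_numpy(),
                db=db,
                n_permutations=n_permutations,
                seed=s,
            )
        )
        row = tests.loc[
            (tests["pair_id"] == "LIGX_RECX")
            & (tests["sender"] == "A")
            & (tests["receiver"] == "B")
        ].iloc[0]
        min_p = 1.0 / (n_permutations + 1)
        rows.append(
            {
                "p_value": float(row["p_value"]),
                "rank": float(row["rank"]),
                "recovered": bool(row["p_value"] <= min_p * (1 + 1e-12) and row["rank"] <= 0.1),
            }
        )
    return pd.DataFrame(rows)


def subtype_recovery_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    n_patients: int = 8,
    effect: float = 5.0,
    n_malignant: int = 100,
) -> dict:
    """LUAD/LUSC label recovery on planted subtype marker programs."""
    n_correct = 0
    n_total = 0
    for s in _child_seeds(seed, n_seeds):
        truth_labels = ["LUAD" if i % 2 == 0 else "LUSC" for i in range(n_patients)]
        cfg = SimulationConfig(
            n_patients=n_patients,
            cell_type_profiles={
                "Cancer": CellTypeProfile(markers=("EPCAM",), malignant=True),
                "T": CellTypeProfile(markers=("CD3D", "CD3E")),
            },
            n_cells_per_type={"Cancer": n_malignant, "T": 50},
            lr_signals=(),
            patient_subtypes=truth_labels,
            subtype_marker_effect=effect,
            seed=s,
        )
        adatas, truth, _ = generate_cohort(cfg)
        for adata, expected in zip(adatas, truth_labels):
            patient = adata.obs["patient"].iloc[0]
            malignant = adata[adata.obs["malignant"].to_numpy()].copy()
            call = subtype_scores(malignant, patient)
            n_correct += call.label == expected
            n_total += 1
    return {"accuracy": n_correct / n_total, "n_patients": n_total}


def qc_boundary_fixture():
    """Deterministic cells sitting exactly on every QC boundary.

    Returns (AnnData, expected surviving cell ids) under the strict
    reading: 200 and 5000 expressed genes survive, 30,000 UMIs survives,
    mito fraction exactly 0.30 survives; 199/5001 genes, 30,001 UMIs and
    0.301 mito are removed.
    """
    from anndata import AnnData
    from scipy import sparse

    n_genes = 5002
    genes = ["MT-1"] + [f"G{i:04d}" for i in range(1, n_genes)]
    rows = {
        "genes_199": {i: 1 for i in range(1, 200)},
        "genes_200": {i: 1 for i in range(1, 201)},
        "genes_5000": {i: 1 for i in range(1, 5001)},
        "genes_5001": {i: 1 for i in range(1, 5002)},
        "umis_30000": {i: 30 for i in range(1, 1001)},
        "umis_30001": {**{i: 30 for i in range(1, 1001)}, 1001: 31},
        "mito_0.300": {0: 300, **{i: 1 for i in range(1, 701)}},
        "mito_0.301": {0: 301, **{i: 1 for i in range(1, 700)}},
    }
    X = sparse.lil_matrix((len(rows), n_genes), dtype=np.int64)
    for r, cols in enumerate(rows.values()):
        for c, v in cols.items():
            X[r, c] = v
    adata = AnnData(X=X.tocsr())
    adata.obs_names = list(rows)
    adata.var_names = genes
    expected = ["genes_200", "genes_5000", "umis_30000", "mito_0.300"]
    return adata, expected


# ---------------------------------------------------------------------------
# brute-force enumeration oracle for the filter/network chain
# ---------------------------------------------------------------------------

def random_interaction_tables(
    rng: np.random.Generator,
    n_patients: int = 8,
    n_pairs: int = 12,
    n_types: int = 4,
    n_genes: int = 10,
) -> dict[str, pd.DataFrame]:
    """Random per-patient test tables mixing specific, promiscuous and null pairs.

    Each pair gets a home (sender, receiver) triple; per patient it is
    either specific there (one significant type-pair, low rank),
    promiscuous (significant in ~a third of type-pairs, high rank) or
    silent, so aggregation boundaries and both network builders are
    exercised on non-trivial retained sets.
    """
    types = [f"T{i}" for i in range(n_types)]
    gene_pool = [f"g{i}" for i in range(n_genes)]
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        l, r = rng.choice(gene_pool, size=2, replace=False)
        if (l, r) not in seen:
            seen.add((l, r))
            pairs.append((l, r))
    home = {
        (l, r): (str(rng.choice(types)), str(rng.choice(types))) for l, r in pairs
    }
    tables = {}
    for p in range(n_patients):
        recs = []
        for l, r in pairs:
            mode = rng.choice(["specific", "promiscuous", "null"], p=[0.7, 0.15, 0.15])
            for s in types:
                for t in types:
                    if mode == "specific":
                        pv = 0.001 if (s, t) == home[(l, r)] else 1.0
                    elif mode == "promiscuous":
                        pv = float(rng.choice([0.001, 1.0], p=[0.35, 0.65]))
                    else:
                        pv = 1.0
                    recs.append(
                        {
                            "pair_id": f"{l}_{r}",
                            "ligand": l,
                            "receptor": r,
                            "sender": s,
                            "receiver": t,
                            "statistic": float(rng.random()),
                            "p_value": pv,
                        }
                    )
        tables[f"P{p}"] = pd.DataFrame(recs)
    return tables


def _brute_force_chain(
    tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    max_rank: float = 0.1,
    min_patients: int = 5,
    min_interactions: int = 2,
):
    """Direct nested-loop enumeration of rank filter, aggregation, networks."""
    triple_patients: dict[tuple, set] = {}
    for patient, t in tables.items():
        ranks: dict[str, float] = {}
        for pair_id in t["pair_id"].unique():
            sub = t[t["pair_id"] == pair_id]
            ranks[pair_id] = (sub["p_value"] < alpha).sum() / len(sub)
        for row in t.itertuples():
            if row.p_value < alpha and ranks[row.pair_id] <= max_rank:
                key = (row.pair_id, row.ligand, row.receptor, row.sender, row.receiver)
                triple_patients.setdefault(key, set()).add(patient)
    retained = {k for k, v in triple_patients.items() if len(v) > min_patients}

    weights: dict[frozenset, int] = {}
    totals: dict[str, int] = {}
    for (_, _, _, s, r) in retained:
        key = frozenset((s, r))
        weights[key] = weights.get(key, 0) + 1
        for t_ in {s, r}:
            totals[t_] = totals.get(t_, 0) + 1
    kept_types = {t_ for t_, n in totals.items() if n >= min_interactions}
    edges = {
        key: w
        for key, w in weights.items()
        if all(t_ in kept_types for t_ in key)
    }

    # union-find over genes of retained pairs
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    lr_edges = set()
    for (_, l, r, _, _) in retained:
        find(l)
        find(r)
        union(l, r)
        lr_edges.add(frozenset((l, r)))
    comps: dict[str, set] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    comp_list = []
    for nodes in comps.values():
        n_edges = sum(1 for e in lr_edges if e <= nodes)
        comp_list.append((nodes, n_edges))
    comp_list.sort(key=lambda c: (-len(c[0]), -c[1], min(c[0])))
    return retained, edges, kept_types, [c[0] for c in comp_list[:4]]


def filters_and_networks_agreement(
    n_instances: int = 100, seed: int = 0, min_interactions: int = 2
) -> dict:
    """Fraction of random instances on which the pipeline's rank filter,
    patient aggregation and both network constructions reproduce the
    brute-force enumeration exactly."""
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    n_agree = 0
    n_nonempty = 0
    for _ in range(n_instances):
        tables = random_interaction_tables(rng)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            retained = ia.aggregate_patients(tables, min_patients=5)
            n_nonempty += len(retained) > 0
            graph = ia.build_celltype_network(retained, min_interactions=min_interactions)
            comps = ia.build_gene_network(retained)
        got_triples = set(
            zip(
                retained["pair_id"],
                retained["ligand"],
                retained["receptor"],
                retained["sender"],
                retained["receiver"],
            )
        )
        got_edges = {
            frozenset((a, b)): d["weight"] for a, b, d in graph.edges(data=True)
        }
        got_nodes = set(graph.nodes)
        got_comps = [set(c.nodes) for c in comps]

        exp_triples, exp_edges, exp_types, exp_comps = _brute_force_chain(
            tables, min_interactions=min_interactions
        )
        ok = (
            got_triples == exp_triples
            and got_edges == exp_edges
            and got_nodes == exp_types
            and got_comps == exp_comps
        )
        n_agree += ok
    return {
        "agreement": n_agree / n_instances,
        "n_instances": n_instances,
        "n_nonempty": n_nonempty,
    }
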