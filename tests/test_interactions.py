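import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from scith.interactions import (
    aggregate_patients,
    build_celltype_network,
    build_gene_network,
    compute_rank,
    default_lr_database,
    permutation_test,
    retained_tests,
)
from scith.validation import filters_and_networks_agreement


def _adata(X, genes):
    adata = AnnData(X=np.asarray(X, dtype=float))
    adata.var_names = genes
    adata.obs_names = [f"C{i}" for i in range(X.shape[0])]
    return adata


@pytest.fixture
def planted_matrix(rng):
    """Ligand expressed only in type A, receptor only in type B."""
    n_per = 20
    genes = ["LIG", "REC", "BG1", "BG2"]
    X = rng.uniform(0.2, 1.0, size=(2 * n_per, 4))
    X[:, 0] = 0.0
    X[:, 1] = 0.0
    X[:n_per, 0] = rng.uniform(2.0, 3.0, size=n_per)  # ligand in A
    X[n_per:, 1] = rng.uniform(2.0, 3.0, size=n_per)  # receptor in B
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return _adata(X, genes), labels


class TestPermutationTest:
    def test_planted_signal_hits_minimal_p(self, planted_matrix):
        adata, labels = planted_matrix
        db = pd.DataFrame({"ligand": ["LIG"], "receptor": ["REC"]})
        tests = permutation_test(adata, labels, db, n_permutations=100, seed=0)
        row = tests[(tests.sender == "A") & (tests.receiver == "B")].iloc[0]
        assert row["p_value"] == pytest.approx(1 / 101)
        # reverse direction is floored: ligand absent from B
        rev = tests[(tests.sender == "B") & (tests.receiver == "A")].iloc[0]
        assert rev["p_value"] == 1.0

    def test_all_zero_ligand_floored_to_p_one(self, rng):
        X = rng.uniform(0.2, 1.0, size=(30, 2))
        X[:, 0] = 0.0
        adata = _adata(X, ["LIG", "REC"])
        labels = np.array(["A"] * 15 + ["B"] * 15)
        db = pd.DataFrame({"ligand": ["LIG"], "receptor": ["REC"]})
        tests = permutation_test(adata, labels, db, n_permutations=50, seed=0)
        assert (tests["p_value"] == 1.0).all()

    def test_p_values_bounded(self, rng):
        X = rng.uniform(0, 1, size=(40, 6))
        genes = [f"g{i}" for i in range(6)]
        labels = np.array(["A", "B"] * 20)
        db = pd.DataFrame({"ligand": genes[:3], "receptor": genes[3:]})
        tests = permutation_test(_adata(X, genes), labels, db, n_permutations=40, seed=1)
        assert (tests["p_value"] >= 1 / 41 - 1e-12).all()
        assert (tests["p_value"] <= 1.0).all()

    def test_seed_reproducible(self, planted_matrix):
        adata, labels = planted_matrix
        db = pd.DataFrame({"ligand": ["LIG"], "receptor": ["REC"]})
        t1 = permutation_test(adata, labels, db, n_permutations=50, seed=3)
        t2 = permutation_test(adata, labels, db, n_permutations=50, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_label_renaming_covariance(self, planted_matrix):
        """Renaming the cell types permutes results without changing them."""
        adata, labels = planted_matrix
        db = pd.DataFrame({"ligand": ["LIG"], "receptor": ["REC"]})
        renamed = np.where(labels == "A", "Z", "Y")
        t1 = permutation_test(adata, labels, db, n_permutations=50, seed=5)
        t2 = permutation_test(adata, renamed, db, n_permutations=50, seed=5)
        m1 = t1.set_index(["sender", "receiver"])["p_value"]
        m2 = t2.set_index(["sender", "receiver"])["p_value"]
        assert m1.loc[("A", "B")] == m2.loc[("Z", "Y")]
        assert m1.loc[("B", "A")] == m2.loc[("Y", "Z")]

    def test_missing_genes_skipped_with_warning(self, planted_matrix):
        adata, labels = planted_matrix
        db = pd.DataFrame(
            {"ligand": ["LIG", "ABSENT"], "receptor": ["REC", "REC"]}
        )
        with pytest.warns(UserWarning, match="absent"):
            tests = permutation_test(adata, labels, db, n_permutations=20, seed=0)
        assert set(tests["pair_id"]) == {"LIG_REC"}

    def test_single_type_errors(self, rng):
        adata = _adata(rng.uniform(size=(10, 2)), ["L", "R"])
        db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        with pytest.raises(ValueError, match="2 cell types"):
            permutation_test(adata, np.array(["A"] * 10), db, n_permutations=10)


def _tests_frame(p_by_triple, pair_id="L_R", ligand="L", receptor="R"):
    rows = []
    for (s, r), p in p_by_triple.items():
        rows.append(
            {
                "pair_id": pair_id,
                "ligand": ligand,
                "receptor": receptor,
                "sender": s,
                "receiver": r,
                "statistic": 1.0,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


class TestRankFilter:
    def test_rank_arithmetic(self):
        types = [f"T{i}" for i in range(10)]
        triples = {(s, r): 1.0 for s in types for r in types}
        triples[("T0", "T1")] = 0.001
        tests = compute_rank(_tests_frame(triples))
        assert tests["rank"].iloc[0] == pytest.approx(0.01)
        assert len(retained_tests(tests)) == 1

    def test_promiscuous_pair_discarded(self):
        types = [f"T{i}" for i in range(10)]
        triples = {(s, r): 1.0 for s in types for r in types}
        for i in range(15):
            triples[(types[i % 10], types[i // 10])] = 0.001
        tests = compute_rank(_tests_frame(triples))
        assert tests["rank"].iloc[0] == pytest.approx(0.15)
        assert len(retained_tests(tests)) == 0

    def test_no_significant_gives_rank_zero(self):
        triples = {("A", "B"): 0.8, ("B", "A"): 1.0}
        tests = compute_rank(_tests_frame(triples))
        assert (tests["rank"] == 0).all()
        assert len(retained_tests(tests)) == 0


class TestAggregatePatients:
    def _cohort(self, n_significant, n_patients=8):
        types = ["A", "B", "C", "D"]
        tables = {}
        for i in range(n_patients):
            triples = {(s, r): 1.0 for s in types for r in types}
            if i < n_significant:
                triples[("A", "B")] = 0.001  # rank 1/16, retained per patient
            tables[f"P{i}"] = _tests_frame(triples)
        return tables

    def test_exactly_five_patients_dropped(self):
        retained = aggregate_patients(self._cohort(5), min_patients=5)
        assert len(retained) == 0

    def test_six_patients_retained(self):
        retained = aggregate_patients(self._cohort(6), min_patients=5)
        assert len(retained) == 1
        assert retained["n_patients"].iloc[0] == 6

    def test_group_fractions_annotated(self):
        groups = {f"P{i}": ("LUADm" if i < 4 else "LUSCn") for i in range(8)}
        retained = aggregate_patients(self._cohort(6), min_patients=5, groups=groups)
        assert retained["frac_LUADm"].iloc[0] == pytest.approx(1.0)
        assert retained["frac_LUSCn"].iloc[0] == pytest.approx(0.5)


class TestNetworks:
    def _retained(self, triples):
        rows = []
        for i, (l, r, s, t) in enumerate(triples):
            rows.append(
                {
                    "pair_id": f"{l}_{r}",
                    "ligand": l,
                    "receptor": r,
                    "sender": s,
                    "receiver": t,
                    "n_patients": 6,
                }
            )
        return pd.DataFrame(rows)

    def test_celltype_network_counts(self):
        retained = self._retained(
            [("l1", "r1", "A", "B"), ("l2", "r2", "A", "B"), ("l3", "r3", "B", "A"),
             ("l4", "r4", "A", "C")]
        )
        g = build_celltype_network(retained, min_interactions=1)
        assert g["A"]["B"]["weight"] == 3
        assert g["A"]["C"]["weight"] == 1

    def test_node_threshold_drops_type(self):
        retained = self._retained(
            [("l1", "r1", "A", "B"), ("l2", "r2", "B", "A"), ("l3", "r3", "A", "C")]
        )
        g = build_celltype_network(retained, min_interactions=2)
        assert set(g.nodes) == {"A", "B"}

    def test_gene_network_components(self):
        retained = self._retained(
            [("a", "b", "A", "B"), ("b", "c", "A", "B"), ("x", "y", "A", "B")]
        )
        comps = build_gene_network(retained)
        assert [set(c.nodes) for c in comps] == [{"a", "b", "c"}, {"x", "y"}]

    def test_empty_retained_set(self):
        empty = pd.DataFrame(
            columns=["pair_id", "ligand", "receptor", "sender", "receiver"]
        )
        with pytest.warns(UserWarning, match="empty"):
            assert build_gene_network(empty) == []
        with pytest.warns(UserWarning, match="empty"):
            assert build_celltype_network(empty).number_of_nodes() == 0

    def test_chain_matches_bruteforce_enumeration(self):
        result = filters_and_networks_agreement(n_instances=20, seed=99)
        assert result["agreement"] == 1.0
        assert result["n_nonempty"] > 0


class TestDefaultDatabase:
    def test_unique_ids_and_nonempty_genes(self):
        db = default_lr_database()
        assert db["pair_id"].is_unique
        assert (db["ligand"].str.len() > 0).all()
        assert (db["receptor"].str.len() > 0).all()
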