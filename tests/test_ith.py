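import numpy as np
import pandas as pd
import pytest

from scith.cna import CNAParams, infer_cna, subsample_for_viz
from scith.ith import (
    compare_groups,
    compute_ith,
    correlate_ith_composition,
    ith_score,
    pairwise_pearson,
)
from scith.qc import lognormalize
from scith.simulate import CellTypeProfile, CNASegment, SimulationConfig, generate_cohort


def _iqr_oracle(values):
    """Brute-force sort-and-interpolate quartiles (linear interpolation)."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def quantile(q):
        pos = (n - 1) * q
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return quantile(0.75) - quantile(0.25)


def _pearson_oracle(x, y):
    """Direct covariance-formula Pearson correlation."""
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPairwisePearson:
    def test_identical_cells_give_ones(self):
        X = np.tile([1.0, 2.0, 5.0, 0.5], (3, 1))
        np.testing.assert_allclose(pairwise_pearson(X), 1.0, atol=1e-12)

    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        X = np.vstack([x, -x, x])
        r = pairwise_pearson(X)
        # pairs in (0,1), (0,2), (1,2) order
        np.testing.assert_allclose(r, [-1.0, 1.0, -1.0], atol=1e-12)

    def test_matches_covariance_oracle(self, rng):
        X = rng.normal(size=(5, 10))
        r = pairwise_pearson(X)
        expected = [
            _pearson_oracle(X[i], X[j])
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        np.testing.assert_allclose(r, expected, atol=1e-12)

    def test_constant_rows_excluded_with_warning(self, rng):
        X = np.vstack([rng.normal(size=(3, 6)), np.full(6, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            r = pairwise_pearson(X)
        assert len(r) == 3  # C(3,2) among the non-constant rows

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            pairwise_pearson(rng.normal(size=(2, 5)))


class TestITHScore:
    def test_point_mass_is_zero(self):
        assert ith_score([0.7] * 10) == 0.0

    def test_linear_interpolation_example(self):
        assert ith_score([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.15, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ith_score([])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            v = rng.uniform(-1, 1, size=rng.integers(3, 50))
            assert ith_score(v) == pytest.approx(_iqr_oracle(v), abs=1e-12)


class TestComputeITH:
    def test_near_copies_score_near_zero(self, rng):
        base = rng.normal(size=60)
        profiles = base + rng.normal(0, 0.01, size=(20, 60))
        res = compute_ith("P", profiles, profiles)
        assert res.ith_cna < 0.02 and res.ith_gex < 0.02

    def test_affine_invariance(self, rng):
        """Pearson invariance: per-cell affine transforms leave scores unchanged."""
        X = rng.normal(size=(8, 30))
        scale = rng.uniform(0.5, 3.0, size=(8, 1))
        shift = rng.normal(size=(8, 1))
        a = compute_ith("P", X, X)
        b = compute_ith("P", scale * X + shift, X)
        assert a.ith_cna == pytest.approx(b.ith_cna, abs=1e-12)

    def test_deterministic_on_duplicate_input(self, rng):
        X = rng.normal(size=(10, 20))
        assert compute_ith("P", X, X).ith_cna == compute_ith("P", X, X).ith_cna

    def test_undefined_below_three_cells(self, rng):
        res = compute_ith("P", rng.normal(size=(2, 10)), rng.normal(size=(2, 10)))
        assert not res.defined and np.isnan(res.ith_cna)

    def test_divergent_clones_raise_score(self):
        """Two divergent clones yield higher ITH_CNA than one homogeneous clone."""
        wins = 0
        n_rep = 10
        for s in range(n_rep):
            base = dict(
                n_patients=2,
                cell_type_profiles={
                    "Cancer": CellTypeProfile(markers=(), malignant=True),
                    "Stromal": CellTypeProfile(markers=()),
                },
                n_cells_per_type={"Cancer": 120, "Stromal": 80},
                patient_clones=[2, 1],
                cna_segments=(
                    CNASegment("chr1", 20, 150, 2.0, clone=0),
                    CNASegment("chr2", 20, 150, 0.5, clone=1),
                ),
                lr_signals=(),
                marker_baseline_mean=None,
                seed=s,
            )
            adatas, _, _ = generate_cohort(SimulationConfig(**base))
            scores = []
            for adata in adatas:
                norm = lognormalize(adata)
                cna = infer_cna(norm, adata.obs["malignant"].to_numpy(), CNAParams())
                mal = cna.obs["malignant"].to_numpy()
                scores.append(ith_score(pairwise_pearson(cna.X[mal])))
            wins += scores[0] > scores[1]
        assert wins >= 0.95 * n_rep

    def test_monotone_in_clone_divergence(self):
        """Median ITH_CNA rises with the divergent clone's fold change."""
        medians = []
        for fold in [1.2, 1.6, 2.0]:
            scores = []
            for s in range(8):
                cfg = SimulationConfig(
                    n_patients=1,
                    cell_type_profiles={
                        "Cancer": CellTypeProfile(markers=(), malignant=True),
                        "Stromal": CellTypeProfile(markers=()),
                    },
                    n_cells_per_type={"Cancer": 150, "Stromal": 80},
                    patient_clones=[2],
                    cna_segments=(CNASegment("chr1", 20, 150, fold, clone=1),),
                    lr_signals=(),
                    marker_baseline_mean=None,
                    seed=1000 + s,
                )
                adatas, _, _ = generate_cohort(cfg)
                norm = lognormalize(adatas[0])
                cna = infer_cna(norm, adatas[0].obs["malignant"].to_numpy(), CNAParams())
                mal = cna.obs["malignant"].to_numpy()
                scores.append(ith_score(pairwise_pearson(cna.X[mal])))
            medians.append(np.median(scores))
        assert medians[0] <= medians[1] <= medians[2]

    def test_subsampling_stability(self):
        """ITH_CNA from 100 subsampled cells stays within 0.05 of the full score."""
        cfg = SimulationConfig(
            n_patients=1,
            cell_type_profiles={
                "Cancer": CellTypeProfile(markers=(), malignant=True),
                "Stromal": CellTypeProfile(markers=()),
            },
            n_cells_per_type={"Cancer": 300, "Stromal": 150},
            patient_clones=[2],
            cna_segments=(
                CNASegment("chr1", 20, 150, 2.0, clone=0),
                CNASegment("chr2", 20, 150, 0.5, clone=1),
            ),
            lr_signals=(),
            marker_baseline_mean=None,
            seed=77,
        )
        adatas, _, _ = generate_cohort(cfg)
        norm = lognormalize(adatas[0])
        cna = infer_cna(norm, adatas[0].obs["malignant"].to_numpy(), CNAParams())
        mal = cna.obs["malignant"].to_numpy()
        full = ith_score(pairwise_pearson(cna.X[mal]))
        diffs = []
        for s in range(20):
            sub = subsample_for_viz(cna, CNAParams(), seed=s)
            diffs.append(abs(ith_score(pairwise_pearson(sub.X)) - full))
        assert np.median(diffs) < 0.05


def _ith_table(values, patients=None):
    patients = patients or [f"P{i}" for i in range(len(values))]
    return pd.DataFrame(
        {
            "ith_cna": values,
            "ith_gex": values,
            "n_malignant_cells": 100,
            "defined": True,
        },
        index=pd.Index(patients, name="patient"),
    )


class TestCompareGroups:
    def test_fully_separated_small_groups_exact_p(self):
        """{1,2,3} vs {10,11,12}: minimal attainable exact two-sided p = 0.1."""
        table = _ith_table([1, 2, 3, 10, 11, 12])
        groups = pd.Series(
            ["LUSCn"] * 3 + ["LUADm"] * 3, index=table.index
        )
        out = compare_groups(table, groups, scores=("ith_cna",), pairs=(("LUSCn", "LUADm"),))
        assert out["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        table = _ith_table([1, 2, 3, 1, 2, 3])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=table.index)
        out = compare_groups(table, groups, scores=("ith_cna",), pairs=(("A", "B"),))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_small_group_skipped_with_warning(self):
        table = _ith_table([1, 2, 3, 4])
        groups = pd.Series(["A", "A", "A", "B"], index=table.index)
        with pytest.warns(UserWarning, match="skipping"):
            out = compare_groups(table, groups, scores=("ith_cna",), pairs=(("A", "B"),))
        assert len(out) == 0


class TestCorrelateComposition:
    def test_linear_relation_gives_r_one(self):
        table = _ith_table([0.1, 0.2, 0.3, 0.4, 0.5])
        prop = 0.1 + 0.5 * table["ith_gex"]
        comp = pd.DataFrame(
            {"Neutrophil": prop, "Rest": 1 - prop}, index=table.index
        )
        out = correlate_ith_composition(table, comp)
        assert out.loc["Neutrophil", "r"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc["Rest", "r"] == pytest.approx(-1.0, abs=1e-9)

    def test_row_sum_validation(self):
        table = _ith_table([0.1, 0.2, 0.3, 0.4])
        comp = pd.DataFrame({"A": [0.5] * 4, "B": [0.4] * 4}, index=table.index)
        with pytest.raises(ValueError, match="sum to 1"):
            correlate_ith_composition(table, comp)

    def test_too_few_patients_errors(self):
        table = _ith_table([0.1, 0.2, 0.3])
        comp = pd.DataFrame({"A": [0.5] * 3, "B": [0.5] * 3}, index=table.index)
        with pytest.raises(ValueError, match="at least 4"):
            correlate_ith_composition(table, comp)

    def test_planted_effect_recovered(self, rng):
        """Neutrophil fraction 0.05 + 0.5*ITH + noise -> significant positive r."""
        ith_values = rng.uniform(0.05, 0.6, size=20)
        table = _ith_table(list(ith_values))
        neut = 0.05 + 0.5 * ith_values + rng.normal(0, 0.02, size=20)
        neut = np.clip(neut, 0.01, 0.9)
        comp = pd.DataFrame(
            {"Neutrophil": neut, "Rest": 1 - neut}, index=table.index
        )
        out = correlate_ith_composition(table, comp)
        assert out.loc["Neutrophil", "r"] > 0.5
        assert out.loc["Neutrophil", "significant"]

    def test_permuted_proportions_null(self, rng):
        """Permuting proportions kills the planted association (|r| small on average)."""
        ith_values = rng.uniform(0.05, 0.6, size=30)
        table = _ith_table(list(ith_values))
        neut = 0.05 + 0.5 * ith_values
        rs = []
        for _ in range(50):
            perm = rng.permutation(neut)
            comp = pd.DataFrame(
                {"Neutrophil": perm, "Rest": 1 - perm}, index=table.index
            )
            out = correlate_ith_composition(table, comp)
            rs.append(out.loc["Neutrophil", "r"])
        assert abs(np.mean(rs)) < 0.15
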