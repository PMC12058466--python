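"""Intragroup/intrabatch variation metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from protnorm.metrics import (
    hierarchical_clustering,
    intragroup_pearson,
    pca_embed,
    pmad,
    pmad_reduction,
    silhouette_coefficients,
    batch_condition_report,
)

from conftest import make_dataset


def brute_force_pmad(matrix, group_cols, constant=1.4826):
    mads = []
    for pid in matrix.index:
        vals = matrix.loc[pid, group_cols].dropna().to_numpy()
        if vals.size < 2:
            continue
        med = np.median(vals)
        mads.append(constant * np.median(np.abs(vals - med)))
    return float(np.mean(mads))


def brute_force_silhouette(emb, labels):
    out = {}
    for j in emb.index:
        own = [k for k in emb.index if labels[k] == labels[j] and k != j]
        if not own:
            out[j] = 0.0
            continue
        d = lambda a, b: np.linalg.norm(emb.loc[a] - emb.loc[b])
        a = np.mean([d(j, k) for k in own])
        b = min(
            np.mean([d(j, k) for k in emb.index if labels[k] == g])
            for g in set(labels) - {labels[j]}
        )
        out[j] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return pd.Series(out)


class TestPmad:
    def test_hand_example(self):
        # protein values (1,3) and (2,2): MADs 1.4826 and 0 -> PMAD 0.7413
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 2.0]}, index=["p1", "p2"])
        assert pmad(m, {"g": ["s1", "s2"]})["g"] == pytest.approx(0.7413)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            X = rng.normal(25, 2, (50, 8))
            X[rng.random((50, 8)) < 0.1] = np.nan
            m = pd.DataFrame(X, columns=[f"s{j}" for j in range(8)])
            m.index = [f"p{i}" for i in range(50)]
            groups = {"g1": [f"s{j}" for j in range(4)], "g2": [f"s{j}" for j in range(4, 8)]}
            res = pmad(m, groups)
            for g, cols in groups.items():
                assert res[g] == pytest.approx(brute_force_pmad(m, cols), abs=1e-12)

    def test_location_invariance_and_zero_on_identical_replicates(self, rng):
        X = rng.normal(25, 2, (30, 4))
        m = pd.DataFrame(X, columns=list("abcd"))
        g = {"g": list("abcd")}
        assert pmad(m + 7.5, g)["g"] == pytest.approx(pmad(m, g)["g"])
        ident = pd.DataFrame(np.tile(X[:, :1], (1, 4)), columns=list("abcd"))
        assert pmad(ident, g)["g"] == 0.0

    def test_single_sample_group_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pmad(m, {"g1": ["a"], "g2": ["b"]})


class TestPmadReduction:
    def test_formula_cases(self):
        norm = pd.Series({"g": 0.25})
        base = pd.Series({"g": 0.5})
        assert pmad_reduction(norm, base)["g"] == pytest.approx(50.0)
        assert pmad_reduction(base, base)["g"] == pytest.approx(0.0)
        assert pmad_reduction(pd.Series({"g": 0.6}), base)["g"] == pytest.approx(-20.0)

    def test_zero_baseline_is_missing(self):
        out = pmad_reduction(pd.Series({"g": 0.1}), pd.Series({"g": 0.0}))
        assert np.isnan(out["g"])


class TestPearson:
    def test_duplicate_and_negated_samples(self):
        x = np.linspace(0, 1, 20)
        m = pd.DataFrame({"a": x, "b": x, "c": -x})
        res = intragroup_pearson(m, {"g": ["a", "b", "c"]})
        r = res.set_index(["sample_1", "sample_2"])["r"]
        assert r[("a", "b")] == pytest.approx(1.0)
        assert r[("a", "c")] == pytest.approx(-1.0)

    def test_fixed_pair_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 3.0, 3.0, 7.0, 8.0])
        m = pd.DataFrame({"a": x, "b": y})
        r = intragroup_pearson(m, {"g": ["a", "b"]})["r"].iloc[0]
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_pair_with_too_few_shared_values_skipped(self):
        m = pd.DataFrame(
            {"a": [1.0, np.nan, np.nan, 2.0], "b": [np.nan, 1.0, 2.0, 3.0]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = intragroup_pearson(m, {"g": ["a", "b"]})
        assert res.empty


class TestPcaEmbed:
    def test_separated_clusters_split_on_pc1(self, rng):
        X = rng.normal(0, 0.1, (50, 6))
        X[:, 3:] += 5.0
        m = pd.DataFrame(X + 25.0, columns=[f"s{j}" for j in range(6)])
        emb = pca_embed(m, k=2)
        gap = abs(emb.iloc[3:]["PC1"].mean() - emb.iloc[:3]["PC1"].mean())
        within = max(emb.iloc[:3]["PC1"].std(), emb.iloc[3:]["PC1"].std())
        assert gap > 5 * within

    def test_duplicated_sample_gets_duplicated_scores(self, rng):
        X = rng.normal(25, 2, (40, 4))
        X[:, 1] = X[:, 0]
        emb = pca_embed(pd.DataFrame(X, columns=list("abcd")), k=3)
        assert np.allclose(emb.loc["a"], emb.loc["b"], atol=1e-9)

    def test_too_few_complete_proteins_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, np.nan]})
        with pytest.raises(ValueError, match="complete proteins"):
            pca_embed(m, k=3)


class TestSilhouette:
    def test_one_dimensional_hand_example(self):
        emb = pd.DataFrame({"PC1": [0.0, 1.0, 10.0, 11.0]}, index=list("wxyz"))
        res = silhouette_coefficients(emb, {"A": ["w", "x"], "B": ["y", "z"]})
        assert res.per_sample["w"] == pytest.approx((10.5 - 1.0) / 10.5)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            emb = pd.DataFrame(
                rng.normal(0, 1, (10, 3)), index=[f"s{j}" for j in range(10)]
            )
            labels = pd.Series(
                rng.permutation(["A"] * 4 + ["B"] * 3 + ["C"] * 3), index=emb.index
            )
            res = silhouette_coefficients(emb, labels)
            brute = brute_force_silhouette(emb, labels)
            assert np.allclose(res.per_sample, brute[res.per_sample.index], atol=1e-12)

    def test_coincident_groups_score_near_zero(self, rng):
        # duplicated point clouds: each sample's nearest foreign point is its
        # own duplicate, so S = -1/n per sample, vanishing with group size
        n = 40
        pts = rng.normal(0, 1, (n, 2))
        emb = pd.DataFrame(
            np.vstack([pts, pts]), index=[f"s{j}" for j in range(2 * n)]
        )
        labels = pd.Series(["A"] * n + ["B"] * n, index=emb.index)
        assert abs(silhouette_coefficients(emb, labels).overall) < 0.05

    def test_single_group_rejected(self, rng):
        emb = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"))
        with pytest.raises(ValueError, match="2 groups"):
            silhouette_coefficients(emb, pd.Series(["A"] * 4, index=emb.index))


class TestBatchConditionReport:
    def test_pure_batch_vs_pure_condition_structure(self, rng):
        base = rng.uniform(20, 30, 60)
        batch_off = {"b1": 2.0, "b2": -2.0}
        conds = ["A", "B"] * 4
        batches = ["b1"] * 4 + ["b2"] * 4
        Xb = np.column_stack(
            [base + batch_off[b] + rng.normal(0, 0.1, 60) for b in batches]
        )
        m = pd.DataFrame(Xb, columns=[f"s{j}" for j in range(8)])
        cond = pd.Series(conds, index=m.columns)
        bat = pd.Series(batches, index=m.columns)
        rep = batch_condition_report(m, cond, bat)
        assert rep["batch_coefficient"] > rep["condition_coefficient"]
        cond_off = {"A": 2.0, "B": -2.0}
        Xc = np.column_stack(
            [base + cond_off[c] + rng.normal(0, 0.1, 60) for c in conds]
        )
        rep2 = batch_condition_report(
            pd.DataFrame(Xc, columns=m.columns), cond, bat
        )
        assert rep2["condition_coefficient"] > rep2["batch_coefficient"]

    def test_structureless_data_scores_near_zero(self, rng):
        X = rng.normal(25, 1, (100, 20))
        m = pd.DataFrame(X, columns=[f"s{j}" for j in range(20)])
        cond = pd.Series(rng.permutation(["A", "B"] * 10), index=m.columns)
        bat = pd.Series(rng.permutation(["b1", "b2"] * 10), index=m.columns)
        rep = batch_condition_report(m, cond, bat)
        assert abs(rep["batch_coefficient"]) < 0.2
        assert abs(rep["condition_coefficient"]) < 0.2


class TestHierarchicalClustering:
    def test_two_batches_recovered_at_two_cluster_cut(self, rng):
        base = rng.uniform(20, 30, 80)
        X = np.column_stack(
            [base + (3.0 if j < 4 else -3.0) + rng.normal(0, 0.1, 80) for j in range(8)]
        )
        m = pd.DataFrame(X, columns=[f"s{j}" for j in range(8)])
        labels = hierarchical_clustering(m)["cut"](2)
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[7]

    def test_identical_samples_merge_at_height_zero(self):
        m = pd.DataFrame(np.tile(np.arange(10.0)[:, None], (1, 4)), columns=list("abcd"))
        Z = hierarchical_clustering(m)["linkage"]
        assert np.allclose(Z[:, 2], 0.0)

    def test_leaf_order_deterministic(self, rng):
        X = rng.normal(25, 1, (30, 6))
        m = pd.DataFrame(X, columns=[f"s{j}" for j in range(6)])
        a = hierarchical_clustering(m)["leaf_order"]
        b = hierarchical_clustering(m)["leaf_order"]
        assert a == b
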