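"""Normalization methods: shared contract plus method-specific oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import protnorm as pn
from protnorm.dataset import Scale, to_log2
from protnorm.normalize import (
    NORMALIZATION_METHODS,
    _vsn_transform,
    normalize,
    vsn_profile_nll,
)

from conftest import make_dataset

ALL_METHODS = sorted(NORMALIZATION_METHODS)


def _method_kwargs(name):
    return {"seed": 7} if name == "eigenms" else {}


class TestSharedContract:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_shape_mask_and_row_order_invariance(self, method, small_raw, rng):
        res = normalize(small_raw, method, **_method_kwargs(method))
        assert res.matrix.shape == small_raw.intensities.shape
        assert res.matrix.isna().equals(small_raw.intensities.isna())
        perm = rng.permutation(small_raw.n_proteins)
        shuffled = small_raw.with_matrix(small_raw.intensities.iloc[perm])
        res2 = normalize(shuffled, method, **_method_kwargs(method))
        restored = res2.matrix.loc[res.matrix.index]
        assert np.allclose(
            res.matrix.fillna(0.0), restored.fillna(0.0), atol=1e-7
        ), f"{method} depends on protein row order"

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_identical_columns_handled_symmetrically(self, method, rng):
        col = rng.uniform(20, 30, 60)
        ds = make_dataset(np.tile(col[:, None], (1, 4)), conditions=list("AABB"))
        res = normalize(pn.to_raw(ds), method, **_method_kwargs(method))
        M = res.matrix.to_numpy()
        assert np.allclose(M, M[:, [0]], atol=1e-6), f"{method} broke column symmetry"

    def test_column_with_too_few_observations_rejected(self):
        X = np.full((5, 3), 25.0)
        X[1:, 2] = np.nan
        with pytest.raises(ValueError, match="s2"):
            normalize(make_dataset(X), "median")

    def test_unknown_method_rejected(self, small_raw):
        with pytest.raises(ValueError, match="unknown normalization"):
            normalize(small_raw, "bogus")


class TestShiftScale:
    def test_median_equalizes_raw_column_medians(self, small_raw):
        res = normalize(small_raw, "median")
        med = np.nanmedian(2.0 ** res.matrix.to_numpy(), axis=0)
        assert np.allclose(med, med[0], rtol=1e-9)

    def test_mean_equalizes_raw_column_means(self, small_raw):
        res = normalize(small_raw, "mean")
        means = np.nanmean(2.0 ** res.matrix.to_numpy(), axis=0)
        assert np.allclose(means, means[0], rtol=1e-9)

    def test_global_variants_equalize_column_sums(self, small_raw):
        for v in ("global_mean", "global_median"):
            res = normalize(small_raw, v)
            sums = np.nansum(2.0 ** res.matrix.to_numpy(), axis=0)
            assert np.allclose(sums, sums[0], rtol=1e-9), v

    def test_mad_centers_and_scales_columns(self, small_raw):
        res = normalize(small_raw, "mad")
        M = res.matrix
        assert np.allclose(M.median(), 0.0, atol=1e-12)
        mads = 1.4826 * (M - M.median()).abs().median()
        assert np.allclose(mads, 1.0, atol=1e-12)


class TestQuantile:
    def test_two_by_two_rank_mean_oracle(self):
        ds = make_dataset(np.array([[1.0, 3.0], [5.0, 7.0]]))
        res = normalize(ds, "quantile")
        assert np.allclose(res.matrix.to_numpy(), [[2.0, 2.0], [6.0, 6.0]])

    def test_complete_columns_share_sorted_values(self, rng):
        ds = make_dataset(rng.uniform(20, 30, (80, 5)))
        res = normalize(ds, "quantile")
        sorted_cols = np.sort(res.matrix.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])

    def test_ties_get_equal_values(self):
        X = np.array([[1.0, 2.0], [1.0, 5.0], [4.0, 9.0]])
        res = normalize(make_dataset(X), "quantile")
        out = res.matrix.to_numpy()
        assert out[0, 0] == out[1, 0]


class TestRlr:
    def test_pure_shift_recovered_exactly(self, rng):
        t = rng.uniform(20, 30, 80)
        X = np.column_stack([t, t, t + 0.5])
        res = normalize(make_dataset(X), "rlr")
        assert np.allclose(res.matrix.iloc[:, 2], t, atol=1e-9)
        a, b = res.params["coefficients"]["s2"]
        assert a == pytest.approx(0.5, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_ma_variant_equals_direct_on_noiseless_shift(self, rng):
        t = rng.uniform(20, 30, 100)
        X = t[:, None] + np.array([0.3, -0.2, 0.1, -0.4])[None, :]
        ra = normalize(make_dataset(X), "rlr")
        rb = normalize(make_dataset(X), "rlr_ma")
        assert np.allclose(ra.matrix, rb.matrix, atol=1e-9)

    def test_cyclic_variant_removes_shift_bias(self, rng):
        t = rng.uniform(20, 30, 150)
        X = t[:, None] + np.array([0.6, -0.4, 0.2, -0.4])[None, :] + rng.normal(0, 0.05, (150, 4))
        res = normalize(make_dataset(X), "rlr_ma_cyc")
        assert np.ptp(res.matrix.mean().to_numpy()) < 0.02


class TestLoess:
    def test_shift_bias_equalizes_column_means(self, rng):
        t = rng.uniform(20, 30, 400)
        X = t[:, None] + np.array([0.4, -0.3, 0.2, -0.3])[None, :] + rng.normal(0, 0.01, (400, 4))
        res = normalize(make_dataset(X), "loess_f")
        assert np.ptp(res.matrix.mean().to_numpy()) < 1e-3
        res_cyc = normalize(make_dataset(X), "loess_cyc", iterations=10)
        assert np.ptp(res_cyc.matrix.mean().to_numpy()) < 1e-3

    def test_intensity_dependent_bias_removed(self, rng):
        A0 = rng.uniform(20, 30, 500)
        X = np.tile(A0[:, None], (1, 4)) + rng.normal(0, 0.01, (500, 4))
        inj = 0.1 * (A0 - A0.mean())
        X[:, 0] += inj
        res = normalize(make_dataset(X), "loess_f")
        resid = res.matrix.iloc[:, 0].to_numpy() - res.matrix.iloc[:, 1].to_numpy()
        interior = (A0 > 22) & (A0 < 28)
        assert np.abs(resid[interior]).mean() < 0.10 * np.abs(inj[interior]).mean()


class TestTmm:
    def test_scaled_column_equalized_exactly(self, rng):
        col = 2.0 ** rng.uniform(18, 28, 200)
        R = np.column_stack([col, 2.0 * col, col])
        res = normalize(make_dataset(R, scale=Scale.RAW), "tmm")
        assert np.allclose(res.matrix.iloc[:, 0], res.matrix.iloc[:, 1], atol=1e-9)

    def test_factor_geometric_mean_is_one(self, small_raw):
        f = normalize(small_raw, "tmm").params["factors"].to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestVsn:
    def test_pure_scaling_absorbed(self, rng):
        mu = rng.uniform(20, 30, 150)
        V = 2.0 ** mu[:, None] * np.array([1.0, 2.0, 0.5])[None, :]
        res = normalize(make_dataset(V, scale=Scale.RAW), "vsn")
        M = res.matrix.to_numpy()
        Mc = M - M.mean(axis=1, keepdims=True)
        assert np.max(np.abs(Mc - Mc[:, [0]])) < 1e-3

    def test_untrimmed_fit_matches_joint_profile_nll_oracle(self, rng):
        mu = rng.uniform(8, 16, 20)
        V = (
            2.0 ** (mu[:, None] + rng.normal(0, 0.1, (20, 3)))
            * np.array([1.0, 1.5, 0.7])[None, :]
            + rng.uniform(0, 50, (20, 3))
        )
        res = normalize(make_dataset(V, scale=Scale.RAW), "vsn", lts_quantile=1.0)

        def oracle_obj(theta):
            return vsn_profile_nll(V, theta[:3], np.exp(theta[3:]))

        col_med = np.median(V, axis=0)
        x0 = np.concatenate([np.zeros(3), np.log(np.median(col_med) / col_med)])
        best = scipy.optimize.minimize(
            oracle_obj, x0, method="Powell",
            options={"maxiter": 50000, "xtol": 1e-12, "ftol": 1e-14},
        )
        oracle = _vsn_transform(V, best.x[:3], np.exp(best.x[3:]))
        # the model has one exactly flat direction (common additive shift of
        # the transformed matrix), so compare after centering
        diff = res.matrix.to_numpy() - oracle
        assert np.max(np.abs(diff - diff.mean())) < 1e-4


class TestNormics:
    def test_full_selection_equals_median_normalization(self, rng):
        # odd row and column counts: the raw- and log2-scale medians agree
        X = (
            rng.uniform(20, 30, 151)[:, None]
            + np.array([0.5, -0.5, 0.2, -0.2, 0.1])[None, :]
            + rng.normal(0, 0.1, (151, 5))
        )
        ds = make_dataset(X)
        a = normalize(ds, "normics_median", n_invariant=151)
        b = normalize(ds, "median")
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_invariant_set_excludes_regulated_proteins(self, rng):
        X = (
            rng.uniform(20, 30, 150)[:, None]
            + np.array([0.5, -0.5, 0.2, -0.2])[None, :]
            + rng.normal(0, 0.1, (150, 4))
        )
        X[:30, :2] += 3.0  # 20% of proteins strongly condition-regulated
        ds = make_dataset(X, conditions=["A", "A", "B", "B"])
        res = normalize(ds, "normics_median", n_invariant=100)
        selected = set(res.params["invariant_proteins"])
        regulated = {f"p{i:05d}" for i in range(30)}
        assert not (selected & regulated)

    def test_full_selection_vsn_equals_vsn(self, rng):
        mu = rng.uniform(8, 16, 25)
        V = 2.0 ** mu[:, None] * np.array([1.0, 1.4, 0.8])[None, :] + rng.uniform(
            0, 30, (25, 3)
        )
        ds = make_dataset(V, scale=Scale.RAW)
        a = normalize(ds, "normics_vsn", n_invariant=25, lts_quantile=1.0)
        b = normalize(ds, "vsn", lts_quantile=1.0)
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)


class TestEigenMS:
    def test_no_residual_structure_is_identity(self, rng):
        mu = rng.uniform(20, 30, 40)
        cond = np.array([0.0, 0.0, 1.5, 1.5])
        X = mu[:, None] + cond[None, :]
        ds = make_dataset(X, conditions=["A", "A", "B", "B"])
        res = normalize(ds, "eigenms", seed=1)
        assert res.params["n_trends"] == 0
        assert np.allclose(res.matrix, X)

    def test_planted_rank_one_trend_removed(self, rng):
        v = np.array([1, -1, 1, -1, 0.5, -0.5, 1, -1.0])
        v /= np.linalg.norm(v)
        u = rng.normal(0, 1, 60)
        X = rng.uniform(20, 30, 60)[:, None] + np.outer(u, v)
        conds = ["A"] * 4 + ["B"] * 4
        ds = make_dataset(X, conditions=conds)
        res = normalize(ds, "eigenms", seed=1)
        assert res.params["n_trends"] == 1
        out = res.matrix.to_numpy().copy()
        for c in ("A", "B"):
            mask = np.array([x == c for x in conds])
            out[:, mask] -= out[:, mask].mean(axis=1, keepdims=True)
        assert np.linalg.norm(out) < 1e-6


class TestRobNorm:
    def test_noiseless_sample_effects_recovered(self, rng):
        mu = rng.uniform(20, 30, 50)
        s = np.array([0.5, -0.2, 0.3, -0.6])
        s -= s.mean()
        ds = make_dataset(mu[:, None] + s[None, :])
        res = normalize(ds, "robnorm")
        assert np.allclose(res.params["sample_effects"], s, atol=1e-8)
        out = res.matrix.to_numpy()
        assert np.allclose(out, out[:, [0]], atol=1e-8)

    def test_gamma_zero_matches_two_way_least_squares(self, rng):
        # balanced +/-1 residual patterns give every protein the same
        # residual variance, so the sigma-weighted fit equals plain LS
        s = np.array([0.45, -0.25, 0.25, -0.65])
        pats = np.array(
            [[1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1],
             [-1, -1, 1, 1], [-1, 1, -1, 1], [-1, 1, 1, -1]],
            dtype=float,
        )
        X = rng.uniform(20, 30, 30)[:, None] + s[None, :] + np.tile(pats, (5, 1)) * 0.3
        res = normalize(make_dataset(X), "robnorm", gamma=0.0, tol=1e-12, max_iter=2000)
        ls = X.mean(axis=0) - X.mean()
        assert np.allclose(res.params["sample_effects"], ls, atol=1e-6)

    def test_density_power_weighting_resists_contamination(self):
        errs = {0.0: [], 0.5: []}
        for seed in range(10):
            rg = np.random.default_rng(seed)
            n = 1000
            mu = rg.uniform(20, 30, n)
            s = rg.normal(0, 0.5, 8)
            s -= s.mean()
            X = mu[:, None] + s[None, :] + rg.normal(0, 0.3, (n, 8))
            contaminated = rg.choice(n, size=n // 5, replace=False)
            X[np.ix_(contaminated, [6, 7])] += 4.0
            ds = make_dataset(X, conditions=["A"] * 6 + ["B"] * 2)
            for g in (0.0, 0.5):
                res = normalize(ds, "robnorm", gamma=g)
                errs[g].append(
                    np.max(np.abs(res.params["sample_effects"].to_numpy() - s))
                )
        assert max(errs[0.5]) < 0.05
        assert np.mean(errs[0.0]) > np.mean(errs[0.5])


class TestSharedShiftRemoval:
    @pytest.mark.parametrize(
        "method", ["mean", "median", "rlr", "loess_f", "robnorm", "normics_median"]
    )
    def test_shift_bias_equalizes_column_means(self, method, rng):
        noise_sd = 0.05
        X = (
            rng.uniform(20, 30, 300)[:, None]
            + np.array([0.5, -0.4, 0.3, -0.4])[None, :]
            + rng.normal(0, noise_sd, (300, 4))
        )
        res = normalize(make_dataset(X), method)
        assert np.ptp(res.matrix.mean().to_numpy()) < 2 * noise_sd
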