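"""Normalization methods for protein-level intensity data.

All methods share one contract: they accept a :class:`ProteomicsDataset` on
either scale, internally apply the method on the scale it is conventionally
defined on (raw for mean/median/global/TMM/VSN/Normics, log2 for the rest),
and return a :class:`NormalizationResult` whose matrix is always on log2
scale with shape and missingness mask preserved.  Fitted parameters
(per-sample shifts, scale factors, transform coefficients, selected
invariant proteins, removed trends) are retained in ``params`` so the
transform is auditable and re-applicable.

Method families
---------------
* simple sample shifting: ``mean``, ``median``, ``global_mean``,
  ``global_median``, ``mad``, ``normics_median``
* sample-to-reference: ``quantile``, ``rlr``, ``rlr_ma``, ``rlr_ma_cyc``,
  ``loess_f``, ``loess_cyc``, ``tmm``
* variance stabilizing: ``vsn``, ``normics_vsn``
* model based: ``eigenms``, ``robnorm``
* baseline: ``log2`` (no-op log2 transform, the unnormalized reference)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .dataset import ProteomicsDataset, Scale, to_log2, to_raw

__all__ = [
    "NormalizationResult",
    "NORMALIZATION_METHODS",
    "normalize",
    "normalize_all",
    "normalize_shift_scale",
    "normalize_quantile",
    "normalize_rlr",
    "normalize_loess",
    "normalize_tmm",
    "normalize_vsn",
    "normalize_normics",
    "normalize_eigenms",
    "normalize_robnorm",
    "normalize_log2",
]

LOG2 = np.log(2.0)


@dataclass
class NormalizationResult:
    """Named output of one normalization method.

    ``matrix`` is the log2-scale normalized proteins x samples DataFrame
    (missingness mask identical to the input unless noted in ``params``);
    ``params`` holds everything needed to re-apply the transform.
    """

    method: str
    matrix: pd.DataFrame
    params: dict = field(default_factory=dict)

    def as_dataset(self, ds: ProteomicsDataset) -> ProteomicsDataset:
        """Wrap the normalized matrix back into a dataset (log2 scale)."""
        return ds.with_matrix(self.matrix, scale=Scale.LOG2)


def _check_input(ds: ProteomicsDataset) -> None:
    if ds.n_samples < 2 or ds.n_proteins < 2:
        raise ValueError("normalization needs >=2 samples and >=2 proteins")
    counts = ds.intensities.notna().sum(axis=0)
    bad = counts.index[counts < 2].tolist()
    if bad:
        raise ValueError(f"fewer than 2 observed values in sample(s): {bad}")


def _log2_matrix(ds: ProteomicsDataset) -> pd.DataFrame:
    return to_log2(ds).intensities.astype(float)


def _raw_matrix(ds: ProteomicsDataset) -> pd.DataFrame:
    return to_raw(ds).intensities.astype(float)


# ---------------------------------------------------------------------------
# Simple sample shifting
# ---------------------------------------------------------------------------


def normalize_shift_scale(
    ds: ProteomicsDataset, variant: str = "median", rescale_mad: bool = False
) -> NormalizationResult:
    """Column shifting/scaling normalizations.

    ``mean``/``median`` (raw scale): every column is multiplied by
    grand_statistic / column_statistic, where the statistic is the column
    mean/median of observed raw values and the grand value is the same
    statistic over the column statistics.  ``global_mean``/``global_median``:
    identical form with the column *sum* as statistic.  ``mad`` (log2 scale):
    each column is centered at its median and divided by its MAD (consistency
    constant 1.4826); by default no common scale is re-added, which is what
    compresses fold changes under this method (set ``rescale_mad=True`` to
    re-add the grand median).
    """
    _check_input(ds)
    variants = ("mean", "median", "global_mean", "global_median", "mad")
    if variant not in variants:
        raise ValueError(f"variant must be one of {variants}")
    if variant == "mad":
        X = _log2_matrix(ds)
        med = X.median(axis=0)
        mad = 1.4826 * (X - med).abs().median(axis=0)
        if (mad <= 0).any():
            raise ValueError("zero MAD column; cannot scale")
        out = (X - med) / mad
        grand = float(np.median(med))
        if rescale_mad:
            out = out + grand
        return NormalizationResult(
            "mad",
            out,
            {"median": med, "mad": mad, "rescaled": rescale_mad, "grand_median": grand},
        )
    R = _raw_matrix(ds)
    if variant in ("mean", "median"):
        stat = R.mean(axis=0) if variant == "mean" else R.median(axis=0)
        grand = float(stat.mean() if variant == "mean" else stat.median())
    else:
        stat = R.sum(axis=0)
        grand = float(stat.mean() if variant == "global_mean" else stat.median())
    factors = grand / stat
    out = np.log2(R * factors)
    return NormalizationResult(variant, out, {"factors": factors, "grand": grand})


def normalize_log2(ds: ProteomicsDataset) -> NormalizationResult:
    """The unnormalized log2 baseline (no-op beyond the log2 transform)."""
    _check_input(ds)
    return NormalizationResult("log2", _log2_matrix(ds), {})


# ---------------------------------------------------------------------------
# Quantile
# ---------------------------------------------------------------------------


def normalize_quantile(ds: ProteomicsDataset) -> NormalizationResult:
    """Quantile normalization on log2 data.

    The reference quantile profile is the mean over samples of the empirical
    quantile functions; each column's observed values are replaced by the
    reference evaluated at their (average-rank, interpolated) quantile
    positions.  On complete data all columns end up with identical sorted
    values; tied values receive the average of their assigned reference
    values.
    """
    _check_input(ds)
    X = _log2_matrix(ds)
    V = X.to_numpy()
    n, m = V.shape
    grid = np.linspace(0.0, 1.0, max(n, 2))
    # mean of per-column quantile functions on a common grid
    ref = np.zeros_like(grid)
    for j in range(m):
        col = np.sort(V[~np.isnan(V[:, j]), j])
        p = np.linspace(0.0, 1.0, col.size) if col.size > 1 else np.array([0.5])
        ref += np.interp(grid, p, col)
    ref /= m
    out = np.full_like(V, np.nan)
    for j in range(m):
        obs = ~np.isnan(V[:, j])
        col = V[obs, j]
        ranks = scipy.stats.rankdata(col, method="average") - 1.0
        p = ranks / (col.size - 1) if col.size > 1 else np.full(col.size, 0.5)
        out[obs, j] = np.interp(p, grid, ref)
    return NormalizationResult(
        "quantile",
        pd.DataFrame(out, index=X.index, columns=X.columns),
        {"reference_profile": ref},
    )


# ---------------------------------------------------------------------------
# Robust linear regression (Rlr family)
# ---------------------------------------------------------------------------


def _robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Huber M-estimated line y ~ a + b x (c = 1.345); OLS fallback when the
    residual scale is degenerate (exact fits)."""
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid_scale = float(np.median(np.abs(y - ols.fittedvalues)))
    if resid_scale < 1e-10:
        return float(ols.params[0]), float(ols.params[1])
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return float(rlm.params[0]), float(rlm.params[1])


def normalize_rlr(
    ds: ProteomicsDataset, variant: str = "rlr", max_cycles: int = 3
) -> NormalizationResult:
    """Robust linear regression normalization (log2 scale).

    ``rlr``: each sample is regressed on the row-median pseudo-reference and
    replaced by (x - a)/b.  ``rlr_ma``: the robust line is fitted on the MA
    representation (M = x - ref vs A = (x + ref)/2) and the fitted bias
    a + b*A is subtracted.  ``rlr_ma_cyc``: the MA fit is applied to every
    ordered sample pair, corrections halved and applied symmetrically, for
    ``max_cycles`` cycles.
    """
    _check_input(ds)
    if variant not in ("rlr", "rlr_ma", "rlr_ma_cyc"):
        raise ValueError(f"unknown variant {variant!r}")
    X = _log2_matrix(ds)
    V = X.to_numpy().copy()
    params: dict = {"reference": "row median", "variant": variant}
    if variant in ("rlr", "rlr_ma"):
        ref = np.nanmedian(V, axis=1)
        coefs = {}
        for j, col in enumerate(X.columns):
            obs = ~np.isnan(V[:, j]) & ~np.isnan(ref)
            if variant == "rlr":
                a, b = _robust_line(ref[obs], V[obs, j])
                V[obs, j] = (V[obs, j] - a) / b
            else:
                M = V[obs, j] - ref[obs]
                A = (V[obs, j] + ref[obs]) / 2.0
                a, b = _robust_line(A, M)
                V[obs, j] = V[obs, j] - (a + b * A)
            coefs[col] = (a, b)
        params["coefficients"] = coefs
    else:
        m = V.shape[1]
        for _ in range(max_cycles):
            for j, k in itertools.combinations(range(m), 2):
                obs = ~np.isnan(V[:, j]) & ~np.isnan(V[:, k])
                if obs.sum() < 3:
                    continue
                M = V[obs, j] - V[obs, k]
                A = (V[obs, j] + V[obs, k]) / 2.0
                a, b = _robust_line(A, M)
                corr = (a + b * A) / 2.0
                V[obs, j] -= corr
                V[obs, k] += corr
        params["cycles"] = max_cycles
    return NormalizationResult(
        variant, pd.DataFrame(V, index=X.index, columns=X.columns), params
    )


# ---------------------------------------------------------------------------
# Loess (local regression)
# ---------------------------------------------------------------------------


def _loess_fit(A: np.ndarray, M: np.ndarray, span: float) -> np.ndarray:
    """Fitted values of a degree-1 local regression of M on A at the data
    points, with a delta shortcut for speed on large inputs."""
    rng = float(A.max() - A.min())
    fitted = sm.nonparametric.lowess(
        M, A, frac=span, it=2, delta=0.005 * rng, return_sorted=False
    )
    return fitted


def normalize_loess(
    ds: ProteomicsDataset,
    variant: str = "loess_f",
    span: float = 0.7,
    iterations: int = 3,
) -> NormalizationResult:
    """Local regression (loess) normalization on MA representations.

    ``loess_f``: one pass per sample against the row-mean pseudo-reference;
    the loess fit of M = x_j - m on A = (x_j + m)/2 is subtracted, removing
    intensity-dependent bias.  ``loess_cyc``: pairwise MA loess over all
    sample pairs with halved symmetric corrections, ``iterations`` cycles.
    """
    _check_input(ds)
    if variant not in ("loess_f", "loess_cyc"):
        raise ValueError(f"unknown variant {variant!r}")
    X = _log2_matrix(ds)
    V = X.to_numpy().copy()
    if variant == "loess_f":
        ref = np.nanmean(V, axis=1)
        for j in range(V.shape[1]):
            obs = ~np.isnan(V[:, j]) & ~np.isnan(ref)
            A = (V[obs, j] + ref[obs]) / 2.0
            M = V[obs, j] - ref[obs]
            V[obs, j] = V[obs, j] - _loess_fit(A, M, span)
        params = {"span": span, "reference": "row mean"}
    else:
        m = V.shape[1]
        for _ in range(iterations):
            for j, k in itertools.combinations(range(m), 2):
                obs = ~np.isnan(V[:, j]) & ~np.isnan(V[:, k])
                if obs.sum() < 10:
                    continue
                A = (V[obs, j] + V[obs, k]) / 2.0
                M = V[obs, j] - V[obs, k]
                corr = _loess_fit(A, M, span) / 2.0
                V[obs, j] -= corr
                V[obs, k] += corr
        params = {"span": span, "cycles": iterations}
    return NormalizationResult(
        variant, pd.DataFrame(V, index=X.index, columns=X.columns), params
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def normalize_tmm(
    ds: ProteomicsDataset, logratio_trim: float = 0.3, sum_trim: float = 0.05
) -> NormalizationResult:
    """Trimmed mean of M-values scaling (raw scale).

    Library sizes are column sums over observed values; the reference sample
    is the one whose 75th percentile of x/N is closest to the mean of those.
    Per sample, the scaling factor is 2**(precision-weighted mean of M values
    surviving two-sided trims on M and A), with binomial delta-method
    weights.  Factors are rescaled to geometric mean 1 and the matrix is
    divided by the effective sizes N_j * f_j (re-multiplied by their
    geometric mean to keep the overall magnitude), then log2-transformed.
    """
    _check_input(ds)
    R = _raw_matrix(ds)
    V = R.to_numpy()
    N = np.nansum(V, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q75 = np.array(
            [np.nanpercentile(V[:, j] / N[j], 75) for j in range(V.shape[1])]
        )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(V.shape[1])
    for j in range(V.shape[1]):
        if j == ref:
            continue
        obs = ~np.isnan(V[:, j]) & ~np.isnan(V[:, ref])
        obs &= (V[:, j] > 0) & (V[:, ref] > 0)
        x, r = V[obs, j], V[obs, ref]
        M = np.log2((x / N[j]) / (r / N[ref]))
        A = 0.5 * np.log2((x / N[j]) * (r / N[ref]))
        finite = np.isfinite(M) & np.isfinite(A)
        M, A, x, r = M[finite], A[finite], x[finite], r[finite]
        n = M.size
        if n == 0:
            continue
        loM = np.floor(n * logratio_trim) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * sum_trim) + 1
        hiA = n + 1 - loA
        rM = scipy.stats.rankdata(M)
        rA = scipy.stats.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            continue
        w = (N[j] - x) / (N[j] * x) + (N[ref] - r) / (N[ref] * r)
        with np.errstate(divide="ignore"):
            wk = 1.0 / w[keep]
        factors[j] = 2.0 ** (np.sum(wk * M[keep]) / np.sum(wk))
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff = N * factors
    scale = np.exp(np.mean(np.log(eff)))
    out = np.log2(V / eff[None, :] * scale)
    return NormalizationResult(
        "tmm",
        pd.DataFrame(out, index=R.index, columns=R.columns),
        {"factors": pd.Series(factors, index=R.columns),
         "library_sizes": pd.Series(N, index=R.columns),
         "reference_sample": R.columns[ref]},
    )


# ---------------------------------------------------------------------------
# VSN (affine-arsinh variance stabilization)
# ---------------------------------------------------------------------------


def _vsn_transform(V: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.arcsinh(a[None, :] + b[None, :] * V) / LOG2


def vsn_profile_nll(
    V: np.ndarray, a: np.ndarray, b: np.ndarray
) -> float:
    """Profile negative log-likelihood of the affine-arsinh model.

    With protein means profiled out (row means of the transformed matrix),
    the normal-model profile likelihood is (N/2) log RSS minus the sum of
    log transform derivatives (the Jacobian term).  The Jacobian term makes
    the problem identifiable: without it the residual sum of squares can be
    driven to zero by collapsing all b_j toward zero.
    """
    H = _vsn_transform(V, a, b)
    mu = np.nanmean(H, axis=1)
    rss = float(np.nansum((H - mu[:, None]) ** 2))
    arg = a[None, :] + b[None, :] * V
    with np.errstate(invalid="ignore", divide="ignore"):
        log_deriv = np.log(b[None, :] / LOG2) - 0.5 * np.log1p(arg**2)
    n_obs = int(np.sum(~np.isnan(V)))
    jac = float(np.nansum(np.where(np.isnan(V), 0.0, log_deriv)))
    return 0.5 * n_obs * np.log(max(rss, 1e-300)) - jac


def _fit_vsn(
    V: np.ndarray,
    lts_quantile: float,
    n_outer: int,
    fit_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-sample affine-arsinh coefficients (a_j, b_j > 0) by iterated
    least-trimmed likelihood.

    Alternates between (i) selecting the ``lts_quantile`` fraction of
    proteins with smallest row residual SS of the transformed matrix and
    (ii) cyclic per-sample coefficient updates minimizing the profile
    negative log-likelihood (residual term plus Jacobian; see
    :func:`vsn_profile_nll`) over the selected rows.  ``fit_rows`` restricts
    parameter estimation to a row subset (used by the Normics variant); the
    transform itself is applied to all rows.
    """
    if not 0.0 < lts_quantile <= 1.0:
        raise ValueError("lts_quantile must be in (0, 1]")
    n, m = V.shape
    col_med = np.nanmedian(V, axis=0)
    grand = np.median(col_med)
    a = np.zeros(m)
    b = grand / col_med
    rows = np.arange(n) if fit_rows is None else np.asarray(fit_rows)
    W = V[rows]
    for _ in range(n_outer):
        H = _vsn_transform(W, a, b)
        mu = np.nanmean(H, axis=1)
        rss_rows = np.nansum((H - mu[:, None]) ** 2, axis=1)
        n_keep = max(2, int(np.ceil(lts_quantile * rows.size)))
        keep = np.argsort(rss_rows, kind="stable")[:n_keep]
        Wk = W[keep]
        for j in range(m):
            if (~np.isnan(Wk[:, j])).sum() < 2:
                continue

            def obj(theta: np.ndarray) -> float:
                aa, bb = a.copy(), b.copy()
                aa[j], bb[j] = theta[0], np.exp(theta[1])
                return vsn_profile_nll(Wk, aa, bb)

            res = scipy.optimize.minimize(
                obj,
                np.array([a[j], np.log(b[j])]),
                method="Nelder-Mead",
                options={"maxiter": 200, "xatol": 1e-9, "fatol": 1e-11},
            )
            a[j], b[j] = res.x[0], np.exp(res.x[1])
    # joint refinement over all coefficients (the cyclic updates converge
    # slowly once near the optimum because the parameters are coupled
    # through the profiled protein means)
    H = _vsn_transform(W, a, b)
    mu = np.nanmean(H, axis=1)
    rss_rows = np.nansum((H - mu[:, None]) ** 2, axis=1)
    n_keep = max(2, int(np.ceil(lts_quantile * rows.size)))
    Wk = W[np.argsort(rss_rows, kind="stable")[:n_keep]]

    def joint(theta: np.ndarray) -> float:
        return vsn_profile_nll(Wk, theta[:m], np.exp(theta[m:]))

    res = scipy.optimize.minimize(
        joint,
        np.concatenate([a, np.log(b)]),
        method="Powell",
        options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-12},
    )
    a, b = res.x[:m], np.exp(res.x[m:])
    return a, b


def normalize_vsn(
    ds: ProteomicsDataset, lts_quantile: float = 0.9, n_outer: int = 10
) -> NormalizationResult:
    """Variance stabilizing normalization via per-sample affine-arsinh
    transforms h_j(x) = arsinh(a_j + b_j x)/ln 2 fitted by iterated
    least-trimmed squares (raw-scale input, glog2-scale output).

    The transform behaves like log2 at high intensities (absorbing
    multiplicative sample effects through b_j) and is linear near zero, so
    the variance of additive background noise is not inflated.
    """
    _check_input(ds)
    R = _raw_matrix(ds)
    V = R.to_numpy()
    a, b = _fit_vsn(V, lts_quantile, n_outer)
    out = _vsn_transform(V, a, b)
    return NormalizationResult(
        "vsn",
        pd.DataFrame(out, index=R.index, columns=R.columns),
        {"a": pd.Series(a, index=R.columns), "b": pd.Series(b, index=R.columns),
         "lts_quantile": lts_quantile},
    )


# ---------------------------------------------------------------------------
# Normics (invariant-protein normalization)
# ---------------------------------------------------------------------------


def _normics_invariant_set(X: pd.DataFrame, n_invariant: int | None) -> pd.Index:
    """Rank complete proteins by the variance across samples of their
    deviation from the column median; return the most stable ones."""
    dev = X - X.median(axis=0)
    complete = dev.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("Normics needs >=2 complete proteins")
    score = complete.var(axis=1, ddof=1)
    if n_invariant is None:
        n_invariant = min(100, max(2, int(np.ceil(0.1 * X.shape[0]))))
    n_invariant = min(n_invariant, score.size)
    return score.sort_values(kind="stable").index[:n_invariant]


def normalize_normics(
    ds: ProteomicsDataset,
    variant: str = "median",
    n_invariant: int | None = None,
    lts_quantile: float = 0.9,
    n_outer: int = 10,
) -> NormalizationResult:
    """Normics: normalization factors estimated from invariant proteins only.

    Proteins are scored by the variance, across samples, of their deviation
    from the column median (computed on complete log2 rows); the
    ``n_invariant`` most stable proteins form the invariant set S (default
    min(100, 10% of proteins)).  ``median`` variant: each sample is shifted
    so the median over S is a common value.  ``vsn`` variant: the affine-
    arsinh coefficients are fitted on S only and applied to all proteins.
    Excluding regulated (high-variance) proteins keeps the factors from
    being dragged by real biological change.
    """
    _check_input(ds)
    if variant not in ("median", "vsn"):
        raise ValueError(f"unknown variant {variant!r}")
    X = _log2_matrix(ds)
    S = _normics_invariant_set(X, n_invariant)
    if variant == "median":
        med_S = X.loc[S].median(axis=0)
        grand = float(np.median(med_S))
        out = X - med_S + grand
        return NormalizationResult(
            "normics_median",
            out,
            {"invariant_proteins": list(S), "shift": med_S - grand},
        )
    R = _raw_matrix(ds)
    V = R.to_numpy()
    pos = R.index.get_indexer(S)
    a, b = _fit_vsn(V, lts_quantile, n_outer, fit_rows=pos)
    out = _vsn_transform(V, a, b)
    return NormalizationResult(
        "normics_vsn",
        pd.DataFrame(out, index=R.index, columns=R.columns),
        {"invariant_proteins": list(S),
         "a": pd.Series(a, index=R.columns), "b": pd.Series(b, index=R.columns)},
    )


# ---------------------------------------------------------------------------
# EigenMS (SVD residual-trend removal)
# ---------------------------------------------------------------------------


def normalize_eigenms(
    ds: ProteomicsDataset,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 1,
    max_trends: int | None = None,
) -> NormalizationResult:
    """Remove significant systematic residual trends via SVD.

    Complete-case proteins are centered within their condition group; the
    residual matrix is decomposed by SVD and each leading singular value's
    variance fraction is tested against ``n_perm`` within-row permutations of
    the residuals (sequentially on the deflated matrix, stopping at the first
    non-significant trend).  Each protein's group-centered residuals are then
    projected onto the significant right-singular vectors (restricted to its
    observed samples) and the projection is subtracted.  Rows are processed
    in protein-id order internally so results do not depend on input row
    order; deterministic given ``seed``.
    """
    _check_input(ds)
    X = _log2_matrix(ds)
    conds = ds.conditions
    cond_masks = {c: (conds == c).to_numpy() for c in conds.unique()}

    def group_center(M: np.ndarray) -> np.ndarray:
        out = M.copy()
        for mask in cond_masks.values():
            with np.errstate(invalid="ignore"):
                means = np.nanmean(out[:, mask], axis=1)
            out[:, mask] = out[:, mask] - means[:, None]
        return out

    order = X.index.sort_values()
    Xs = X.loc[order].to_numpy()
    complete = ~np.isnan(Xs).any(axis=1)
    R = group_center(Xs[complete])
    m = R.shape[1]
    rng = np.random.default_rng(seed)
    if max_trends is None:
        max_trends = max(1, m - len(cond_masks))
    sig_vectors: list[np.ndarray] = []
    p_values: list[float] = []
    total = float(np.sum(R**2))
    if total >= 1e-12:
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        fracs = S**2 / np.sum(S**2)
        # permutation null: shuffle each row's entries independently and
        # re-apply the group centering, then compare the t-th observed
        # eigenvalue fraction with the t-th fraction of the permuted
        # matrices (no deflation: deflating would shrink the observed
        # matrix's rank but not the null's, inflating every later trend)
        null_fracs = np.empty((n_perm, len(S)))
        for b in range(n_perm):
            keys = rng.random(R.shape)
            perm = np.take_along_axis(R, np.argsort(keys, axis=1), axis=1)
            perm = group_center(perm)
            ev = np.linalg.eigvalsh(perm.T @ perm)[::-1]
            ev = np.maximum(ev, 0.0)
            null_fracs[b] = ev[: len(S)] / max(ev.sum(), 1e-300)
        for t in range(min(max_trends, len(S))):
            if S[t] ** 2 < 1e-12 * total:
                break
            p = (1 + int(np.sum(null_fracs[:, t] >= fracs[t]))) / (1 + n_perm)
            p_values.append(p)
            if p >= alpha:
                break
            v = Vt[t]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            sig_vectors.append(v)
    if not sig_vectors:
        return NormalizationResult(
            "eigenms", X, {"n_trends": 0, "trend_p_values": p_values}
        )
    V = np.column_stack(sig_vectors)
    resid = group_center(Xs)
    out = Xs.copy()
    for i in range(Xs.shape[0]):
        obs = ~np.isnan(Xs[i])
        if obs.sum() <= V.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(V[obs], resid[i, obs], rcond=None)
        out[i, obs] -= V[obs] @ beta
    out_df = pd.DataFrame(out, index=order, columns=X.columns).loc[X.index]
    return NormalizationResult(
        "eigenms",
        out_df,
        {"n_trends": len(sig_vectors), "trends": V, "trend_p_values": p_values},
    )


# ---------------------------------------------------------------------------
# RobNorm (robust density-power sample-effect estimation)
# ---------------------------------------------------------------------------


def normalize_robnorm(
    ds: ProteomicsDataset,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> NormalizationResult:
    """Robust model-based normalization x_ij = mu_i + s_j + eps_ij.

    Sample effects s_j are estimated by density-power-weighted iteration:
    observations far from the current fit (|x - mu_i - s_j| large relative
    to sigma_i) receive exponentially down-weighted influence
    w = exp(-gamma r^2 / (2 sigma_i^2)), so regulated proteins do not drag
    the sample effects.  ``gamma=0`` reduces to variance-weighted least
    squares.  The normalized matrix is x - s (s centered to mean 0).
    """
    _check_input(ds)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    X = _log2_matrix(ds)
    V = X.to_numpy()
    obs = ~np.isnan(V)
    # median-based init: sample effects from column medians, then protein
    # means against the shift-corrected matrix (exact on noiseless x = mu + s)
    col_med = np.nanmedian(V, axis=0)
    s = col_med - col_med.mean()
    mu = np.nanmedian(V - s[None, :], axis=1)
    resid = V - mu[:, None] - s[None, :]
    sigma2 = np.maximum(np.nanvar(resid, axis=1, ddof=0), 1e-6)
    for _ in range(max_iter):
        resid = V - mu[:, None] - s[None, :]
        with np.errstate(invalid="ignore", over="ignore"):
            w = np.exp(-gamma * resid**2 / (2.0 * sigma2[:, None]))
        w = np.where(obs, w, 0.0)
        xs = np.where(obs, V, 0.0)
        mu = np.sum(w * (xs - s[None, :]), axis=1) / np.maximum(
            np.sum(w, axis=1), 1e-12
        )
        wv = w / sigma2[:, None]
        s_new = np.sum(wv * (xs - mu[:, None]), axis=0) / np.maximum(
            np.sum(wv, axis=0), 1e-12
        )
        s_new = s_new - s_new.mean()
        resid = V - mu[:, None] - s_new[None, :]
        # robust scale update: 1.4826 * MAD of residuals per protein, so
        # outlying cells cannot inflate their own sigma and escape the
        # density-power downweighting
        sigma2 = (1.4826 * np.nanmedian(np.abs(np.where(obs, resid, np.nan)),
                                        axis=1)) ** 2
        # absolute floor plus a mild relative floor so that a handful of
        # near-perfectly fitted proteins cannot monopolize the weights
        floor = max(1e-6, 0.01 * float(np.median(sigma2)))
        sigma2 = np.maximum(sigma2, floor)
        delta = float(np.max(np.abs(s_new - s)))
        s = s_new
        if delta < tol:
            break
    out = X - pd.Series(s, index=X.columns)
    return NormalizationResult(
        "robnorm",
        out,
        {"sample_effects": pd.Series(s, index=X.columns), "gamma": gamma},
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

NORMALIZATION_METHODS: dict[str, Callable[..., NormalizationResult]] = {
    "log2": normalize_log2,
    "mean": lambda ds, **kw: normalize_shift_scale(ds, "mean", **kw),
    "median": lambda ds, **kw: normalize_shift_scale(ds, "median", **kw),
    "global_mean": lambda ds, **kw: normalize_shift_scale(ds, "global_mean", **kw),
    "global_median": lambda ds, **kw: normalize_shift_scale(ds, "global_median", **kw),
    "mad": lambda ds, **kw: normalize_shift_scale(ds, "mad", **kw),
    "quantile": normalize_quantile,
    "rlr": lambda ds, **kw: normalize_rlr(ds, "rlr", **kw),
    "rlr_ma": lambda ds, **kw: normalize_rlr(ds, "rlr_ma", **kw),
    "rlr_ma_cyc": lambda ds, **kw: normalize_rlr(ds, "rlr_ma_cyc", **kw),
    "loess_f": lambda ds, **kw: normalize_loess(ds, "loess_f", **kw),
    "loess_cyc": lambda ds, **kw: normalize_loess(ds, "loess_cyc", **kw),
    "tmm": normalize_tmm,
    "vsn": normalize_vsn,
    "normics_median": lambda ds, **kw: normalize_normics(ds, "median", **kw),
    "normics_vsn": lambda ds, **kw: normalize_normics(ds, "vsn", **kw),
    "eigenms": normalize_eigenms,
    "robnorm": normalize_robnorm,
}


def normalize(ds: ProteomicsDataset, method: str, **kwargs) -> NormalizationResult:
    """Apply one normalization method by name (see NORMALIZATION_METHODS)."""
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization method {method!r}; "
            f"valid: {sorted(NORMALIZATION_METHODS)}"
        )
    result = NORMALIZATION_METHODS[method](ds, **kwargs)
    result.method = method
    return result


def normalize_all(
    ds: ProteomicsDataset,
    methods: Iterable[str] | None = None,
    seed: int = 1,
) -> dict[str, NormalizationResult]:
    """Run a set of normalization methods (default: all) on one dataset."""
    if methods is None:
        methods = list(NORMALIZATION_METHODS)
    out = {}
    for name in methods:
        kwargs = {"seed": seed} if name == "eigenms" else {}
        out[name] = normalize(ds, name, **kwargs)
    return out
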