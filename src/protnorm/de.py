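"""Two-group differential expression testing.

Two test families are provided:

* an empirical-Bayes moderated t-test: per-protein residual variances are
  shrunk toward a common prior via a scaled-F hierarchical model whose
  hyperparameters (prior df d0, prior variance s0^2) are estimated by
  method of moments on log variances (digamma/trigamma matching);
* the reproducibility-optimized test statistic (ROTS): a family of
  statistics |mean difference| / (alpha1 + alpha2 * SE) tuned so that
  bootstrap top-k lists are maximally reproducible relative to a permuted
  null, with pooled permutation p-values.

All comparisons are Case - Control on log2 data, so a positive logFC means
higher intensity in the Case group.  P-values are Benjamini-Hochberg
adjusted per (method, comparison) family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

__all__ = [
    "EBHyperparams",
    "DEResult",
    "estimate_eb_hyperparams",
    "moderated_t",
    "rots",
    "bh_adjust",
    "call_de",
]


@dataclass
class EBHyperparams:
    """Prior degrees of freedom and prior variance of the scaled-F variance
    model; ``d0 = inf`` means all variances are shrunk to ``s02``."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if self.s02 <= 0:
            raise ValueError("prior variance s02 must be positive")
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0")


@dataclass
class DEResult:
    """Per-protein DE table for one two-group comparison under one method.

    ``table`` columns: logFC (log2, Case - Control), stat, p, p_adj, call
    (``up``/``down``/``ns``).  Proteins with insufficient replication carry
    NaN p and are excluded from the BH family.
    """

    comparison: str
    method: str
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def de_proteins(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def estimate_eb_hyperparams(s2: np.ndarray, d: float) -> EBHyperparams:
    """Method-of-moments fit of the scaled-F model to residual variances.

    Writing z = log s^2, the model implies E[z] and Var[z] in terms of
    digamma/trigamma functions of d/2 and d0/2; matching the sample moments
    yields d0 and s0^2.  When the observed dispersion of log variances does
    not exceed trigamma(d/2) (no excess variability between proteins), the
    prior df is infinite and every variance shrinks fully to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError(
            f"need >= 10 finite positive variances, got {s2.size}"
        )
    z = np.log(s2)
    e = z - scipy.special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(scipy.special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(
            emean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
        return EBHyperparams(d0=d0, s02=float(s02))
    return EBHyperparams(d0=np.inf, s02=float(np.exp(emean)))


def _two_group_arrays(
    matrix_log2: pd.DataFrame,
    groups: pd.Series | dict,
    case: str,
    control: str,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(groups, dict):
        case_cols, control_cols = list(groups[case]), list(groups[control])
    else:
        case_cols = groups.index[groups == case].tolist()
        control_cols = groups.index[groups == control].tolist()
    if not case_cols or not control_cols:
        raise ValueError(f"empty group in comparison {case}-{control}")
    return (
        matrix_log2[case_cols].to_numpy(dtype=float),
        matrix_log2[control_cols].to_numpy(dtype=float),
    )


def moderated_t(
    matrix_log2: pd.DataFrame,
    groups: pd.Series | dict,
    case: str,
    control: str,
    hyper: EBHyperparams | None = None,
    alpha: float = 0.05,
    logfc_threshold: float = 0.0,
) -> DEResult:
    """Empirical-Bayes moderated t-test for the Case - Control contrast.

    Per protein (requiring >= 2 observed values in each group):
    logFC = mean(Case) - mean(Control); pooled variance s^2 with df d;
    posterior variance s~^2 = (d0 s0^2 + d s^2)/(d0 + d);
    t = logFC / (s~ sqrt(1/n1 + 1/n2)), two-sided p on d0 + d df (standard
    normal when d0 is infinite).  ``hyper=None`` estimates the prior from
    the data; ``d0=0`` recovers the ordinary pooled two-sample t-test.
    """
    A, B = _two_group_arrays(matrix_log2, groups, case, control)
    n1 = (~np.isnan(A)).sum(axis=1)
    n2 = (~np.isnan(B)).sum(axis=1)
    testable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(A, axis=1)
        m2 = np.nanmean(B, axis=1)
        v1 = np.nanvar(A, axis=1, ddof=1)
        v2 = np.nanvar(B, axis=1, ddof=1)
    logfc = m1 - m2
    d = (n1 - 1) + (n2 - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    if hyper is None:
        # hyperparameter fit uses the modal residual df (ties resolved low)
        dmode = float(np.bincount(d[testable].astype(int)).argmax())
        hyper = estimate_eb_hyperparams(s2[testable & (d == dmode)], dmode)
    d0, s02 = hyper.d0, hyper.s02
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s02 + d * s2) / (d0 + d)
            df_total = d0 + d
        t = logfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = np.full(t.shape, np.nan)
    finite_df = np.isfinite(df_total) & testable
    p[finite_df] = 2.0 * scipy.stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    inf_df = ~np.isfinite(df_total) & testable
    p[inf_df] = 2.0 * scipy.stats.norm.sf(np.abs(t[inf_df]))
    table = pd.DataFrame(
        {
            "logFC": np.where(testable, logfc, np.nan),
            "stat": np.where(testable, t, np.nan),
            "p": p,
        },
        index=matrix_log2.index,
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    res = DEResult(
        comparison=f"{case}-{control}",
        method="moderated_t",
        table=table,
        params={"d0": d0, "s02": s02, "n_excluded": int((~testable).sum())},
    )
    return call_de(res, alpha=alpha, logfc_threshold=logfc_threshold)


# ---------------------------------------------------------------------------
# ROTS
# ---------------------------------------------------------------------------


def _rots_stat(
    A: np.ndarray, B: np.ndarray, a1: float, a2: float
) -> np.ndarray:
    """|mean difference| / (a1 + a2 * pooled SE); NaN-aware."""
    n1 = np.maximum((~np.isnan(A)).sum(axis=1), 1)
    n2 = np.maximum((~np.isnan(B)).sum(axis=1), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
        v1 = np.nanvar(A, axis=1, ddof=1)
        v2 = np.nanvar(B, axis=1, ddof=1)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    denom = a1 + a2 * se
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(diff) / denom


def _topk_overlap(u: np.ndarray, v: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Fraction of shared proteins among the top-k of two rankings, per k."""
    ord_u = np.argsort(-u, kind="stable")
    ord_v = np.argsort(-v, kind="stable")
    out = np.empty(ks.size)
    for i, k in enumerate(ks):
        out[i] = len(np.intersect1d(ord_u[:k], ord_v[:k])) / k
    return out


def rots(
    matrix_log2: pd.DataFrame,
    groups: pd.Series | dict,
    case: str,
    control: str,
    B: int = 100,
    K: list[int] | None = None,
    a1_grid: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0),
    n_perm: int = 500,
    seed: int = 1,
    alpha: float = 0.05,
    logfc_threshold: float = 0.0,
) -> DEResult:
    """Reproducibility-optimized test statistic for Case - Control.

    The statistic family d = |x1bar - x2bar| / (a1 + a2 * SE) spans the plain
    difference (a = (1, 0)) and a t-like statistic (a = (0, 1)).  For each
    candidate (a1, a2) and top-list size k, reproducibility is the mean
    top-k overlap across ``B`` within-group bootstrap pairs; the same
    quantity on group-label-permuted data provides the null level and
    spread, and the (a, k) maximizing the standardized excess
    reproducibility Z_k = (R_k - R0_k)/sd(R0_k) is selected.  P-values come
    from ``n_perm`` label permutations of the selected statistic, pooled
    over proteins.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    A, Bm = _two_group_arrays(matrix_log2, groups, case, control)
    n_prot = A.shape[0]
    n1, n2 = A.shape[1], Bm.shape[1]
    n_distinct = scipy.special.comb(n1 + n2, n1)
    if n_distinct < 10:
        raise ValueError(
            "too few samples for label permutations "
            f"({int(n_distinct)} distinct assignments)"
        )
    if K is None:
        K = [k for k in (25, 50, 100, 200, 400) if k <= n_prot // 2] or [
            max(1, n_prot // 4)
        ]
    ks = np.asarray(sorted(set(K)))
    grid = [(1.0, 0.0)] + [(a1, 1.0) for a1 in a1_grid]
    pooled = np.hstack([A, Bm])

    def bootstrap_pair(X: np.ndarray, Y: np.ndarray):
        bi = rng.integers(0, n1, size=n1)
        bj = rng.integers(0, n2, size=n2)
        ci = rng.integers(0, n1, size=n1)
        cj = rng.integers(0, n2, size=n2)
        return (X[:, bi], Y[:, bj]), (X[:, ci], Y[:, cj])

    R = np.zeros((len(grid), ks.size))
    R0 = np.zeros((B, len(grid), ks.size))
    for b in range(B):
        (Xa, Ya), (Xb, Yb) = bootstrap_pair(A, Bm)
        perm = rng.permutation(n1 + n2)
        Pa, Pb = pooled[:, perm[:n1]], pooled[:, perm[n1:]]
        (Na, Ma), (Nb, Mb) = bootstrap_pair(Pa, Pb)
        for gi, (a1, a2) in enumerate(grid):
            u = _rots_stat(Xa, Ya, a1, a2)
            v = _rots_stat(Xb, Yb, a1, a2)
            R[gi] += _topk_overlap(u, v, ks)
            u0 = _rots_stat(Na, Ma, a1, a2)
            v0 = _rots_stat(Nb, Mb, a1, a2)
            R0[b, gi] = _topk_overlap(u0, v0, ks)
    R /= B
    R0_mean = R0.mean(axis=0)
    R0_sd = R0.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (R - R0_mean) / R0_sd
    Z[~np.isfinite(Z)] = -np.inf
    gi, ki = np.unravel_index(np.argmax(Z), Z.shape)
    a1, a2 = grid[gi]
    stat = _rots_stat(A, Bm, a1, a2)

    # pooled permutation p-values for the selected statistic
    null_stats = np.empty((n_perm, n_prot))
    for r in range(n_perm):
        perm = rng.permutation(n1 + n2)
        null_stats[r] = _rots_stat(pooled[:, perm[:n1]], pooled[:, perm[n1:]], a1, a2)
    null_flat = np.sort(null_stats[np.isfinite(null_stats)])
    testable = np.isfinite(stat)
    p = np.full(n_prot, np.nan)
    n_null = null_flat.size
    ge = n_null - np.searchsorted(null_flat, stat[testable], side="left")
    p[testable] = (1.0 + ge) / (1.0 + n_null)

    logfc = np.nanmean(A, axis=1) - np.nanmean(Bm, axis=1)
    table = pd.DataFrame(
        {"logFC": logfc, "stat": stat, "p": p}, index=matrix_log2.index
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    res = DEResult(
        comparison=f"{case}-{control}",
        method="rots",
        table=table,
        params={"alpha1": a1, "alpha2": a2, "k": int(ks[ki]), "Z": float(Z[gi, ki])},
    )
    return call_de(res, alpha=alpha, logfc_threshold=logfc_threshold)


# ---------------------------------------------------------------------------
# Multiple testing and DE calling
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and reinserted as NaN;
    values outside [0, 1] are an error.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = vals.size
    if n == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * n / (np.arange(n) + 1.0)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[mask] = res
    return out


def call_de(
    de: DEResult, alpha: float = 0.05, logfc_threshold: float = 0.0
) -> DEResult:
    """Classify proteins as up/down/ns from adjusted p and logFC.

    ``up``: p_adj < alpha and logFC > threshold; ``down`` symmetric;
    everything else (including untestable proteins) is ``ns``.  The |logFC|
    threshold of 1 is the convention for biological datasets; spike-in
    evaluations use threshold 0.
    """
    if logfc_threshold < 0:
        raise ValueError("logfc_threshold must be >= 0")
    t = de.table
    sig = t["p_adj"] < alpha
    call = pd.Series("ns", index=t.index)
    call[sig & (t["logFC"] > logfc_threshold)] = "up"
    call[sig & (t["logFC"] < -logfc_threshold)] = "down"
    table = t.copy()
    table["call"] = call
    return DEResult(
        comparison=de.comparison,
        method=de.method,
        table=table,
        params={**de.params, "alpha": alpha, "logfc_threshold": logfc_threshold},
    )
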