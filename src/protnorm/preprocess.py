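"""Preprocessing: annotation filtering, missing-value handling, imputation
and group-centroid outlier detection.

Missingness is handled with the MAR/MNAR dichotomy common in protein
quantification: a protein whose values are missing across *all* replicates
of at least one condition is treated as missing-not-at-random (left-censored
low-abundance signal) and imputed from a left-shifted Gaussian; proteins with
scattered missing values are treated as missing-at-random and imputed by
k-nearest-neighbour averaging over similar proteins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ProteomicsDataset, Scale

__all__ = [
    "filter_by_annotation",
    "filter_missing",
    "classify_missingness",
    "impute_mixed",
    "detect_outliers",
    "OutlierReport",
]

log = logging.getLogger(__name__)


def filter_by_annotation(
    ds: ProteomicsDataset, flags: set[str] | frozenset[str]
) -> ProteomicsDataset:
    """Remove proteins carrying any of the selected annotation flags.

    Typical use: drop decoy (``reverse``) and ``contaminant`` entries from a
    MaxQuant-style table.  Row order of the remaining proteins is preserved;
    an unknown flag name is an error.
    """
    flags = set(flags)
    unknown = flags - set(ds.annotations.columns)
    if unknown:
        raise ValueError(
            f"unknown annotation flags {sorted(unknown)}; "
            f"available: {sorted(ds.annotations.columns)}"
        )
    if not flags:
        return ds
    drop = ds.annotations[sorted(flags)].any(axis=1)
    return ds.with_matrix(ds.intensities.loc[~drop])


def filter_missing(
    ds: ProteomicsDataset, min_valid_fraction: float, per: str = "overall"
) -> ProteomicsDataset:
    """Keep proteins with at least ``min_valid_fraction`` observed values.

    ``per="overall"`` applies the threshold to the fraction of observed
    values over all samples; ``per="per_condition"`` requires the criterion
    to hold within every condition.
    """
    if not 0.0 <= min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must be in [0, 1]")
    if per not in ("overall", "per_condition"):
        raise ValueError(f"unknown mode {per!r}")
    observed = ds.intensities.notna()
    if per == "overall":
        keep = observed.mean(axis=1) >= min_valid_fraction
    else:
        keep = pd.Series(True, index=ds.protein_ids)
        for cond, cols in ds.condition_groups().items():
            keep &= observed[cols].mean(axis=1) >= min_valid_fraction
    return ds.with_matrix(ds.intensities.loc[keep])


def classify_missingness(ds: ProteomicsDataset) -> pd.Series:
    """Classify each protein as ``complete``, ``MAR`` or ``MNAR``.

    MNAR: missing across all replicates of at least one condition.
    Complete: no missing value.  MAR: everything else.
    """
    groups = ds.condition_groups()
    if any(len(cols) == 0 for cols in groups.values()):
        raise ValueError("every condition needs at least one sample")
    observed = ds.intensities.notna()
    complete = observed.all(axis=1)
    mnar = pd.Series(False, index=ds.protein_ids)
    for cond, cols in groups.items():
        mnar |= ~observed[cols].any(axis=1)
    out = pd.Series("MAR", index=ds.protein_ids, name="missingness")
    out[mnar] = "MNAR"
    out[complete] = "complete"
    return out


def _knn_impute_row(
    target: np.ndarray,
    candidates: np.ndarray,
    missing_cols: np.ndarray,
    k: int,
) -> tuple[np.ndarray, bool]:
    """Impute missing cells of one row from its k nearest candidate rows.

    Distances are Euclidean over shared observed samples after per-row
    standardization on those samples (so similarity reflects profile shape,
    not absolute abundance); imputed values are unstandardized neighbour
    values.  Returns (filled values per missing col, success flag).
    """
    obs = ~np.isnan(target)
    filled = np.full(missing_cols.size, np.nan)
    ok = False
    # distance to every candidate over shared observed columns
    shared = obs[None, :] & ~np.isnan(candidates)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore"):
        dists = np.full(candidates.shape[0], np.inf)
        for i in np.nonzero(n_shared >= 2)[0]:
            cols = shared[i]
            t = target[cols]
            c = candidates[i, cols]
            ts, cs = t.std(), c.std()
            tz = (t - t.mean()) / ts if ts > 0 else t - t.mean()
            cz = (c - c.mean()) / cs if cs > 0 else c - c.mean()
            dists[i] = np.sqrt(np.mean((tz - cz) ** 2))
    order = np.argsort(dists, kind="stable")
    for m, col in enumerate(missing_cols):
        donors = [
            i for i in order if np.isfinite(dists[i]) and not np.isnan(candidates[i, col])
        ][:k]
        if donors:
            filled[m] = candidates[donors, col].mean()
            ok = True
    return filled, ok and not np.isnan(filled).any()


def impute_mixed(
    ds: ProteomicsDataset,
    k: int = 10,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> ProteomicsDataset:
    """Mixed MAR/MNAR imputation on log2 data.

    MAR proteins: each missing cell becomes the mean, in that sample, of the
    ``k`` nearest proteins (Euclidean distance over shared observed samples).
    MNAR proteins: draws from Normal(m_j - shift*s_j, (width*s_j)^2), where
    m_j and s_j are the observed mean and SD of sample j — the left-shifted
    Gaussian convention for censored low-abundance values.  Deterministic
    given ``seed``; observed cells are never touched.
    """
    if ds.scale is not Scale.LOG2:
        raise ValueError("impute_mixed requires log2-scale data")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    X = ds.intensities.to_numpy(dtype=float).copy()
    classes = classify_missingness(ds)
    m_j = np.nanmean(X, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s_j = np.nanstd(X, axis=0, ddof=1)
    s_j = np.where(np.isfinite(s_j), s_j, 0.0)  # single-observation column

    def mnar_draw(row: int, cols: np.ndarray) -> None:
        X[row, cols] = rng.normal(
            m_j[cols] - shift * s_j[cols], width * s_j[cols]
        )

    complete_rows = X[~np.isnan(X).any(axis=1)]
    fallback = 0
    row_pos = {pid: i for i, pid in enumerate(ds.protein_ids)}
    for pid, cls in classes.items():
        if cls == "complete":
            continue
        i = row_pos[pid]
        cols = np.nonzero(np.isnan(X[i]))[0]
        if cls == "MNAR":
            mnar_draw(i, cols)
            continue
        # MAR: kNN over other proteins (complete rows are the donor pool)
        if (~np.isnan(X[i])).sum() < 2 or complete_rows.shape[0] == 0:
            fallback += 1
            mnar_draw(i, cols)
            continue
        filled, ok = _knn_impute_row(X[i], complete_rows, cols, k)
        if ok:
            X[i, cols] = filled
        else:
            fallback += 1
            good = ~np.isnan(filled)
            X[i, cols[good]] = filled[good]
            mnar_draw(i, cols[~good])
    if fallback:
        log.info("impute_mixed: %d MAR proteins fell back to MNAR draws", fallback)
    out = pd.DataFrame(X, index=ds.protein_ids, columns=ds.intensities.columns)
    return ds.with_matrix(out)


@dataclass
class OutlierReport:
    """Per-sample distance to the group centroid and Tukey-fence flags."""

    distances: pd.Series  # per sample
    thresholds: pd.Series  # per group
    flagged: pd.Series  # per sample, bool
    groups: pd.Series  # per sample group label

    def flagged_samples(self) -> list[str]:
        return self.flagged.index[self.flagged].tolist()


def detect_outliers(
    ds: ProteomicsDataset, coef: float = 1.5
) -> OutlierReport:
    """Group-centroid outlier detection on log2 data.

    For each condition group, every sample's Euclidean distance (over
    complete-case proteins) to the group centroid is computed; samples whose
    distance exceeds Q3 + coef*IQR of their group's distances are flagged.
    Quartiles use linear interpolation.  Groups of size 1 are never flagged.
    """
    if ds.scale is not Scale.LOG2:
        raise ValueError("detect_outliers requires log2-scale data")
    X = ds.intensities.dropna(axis=0)
    if X.empty:
        raise ValueError("no complete-case proteins for outlier detection")
    groups = ds.conditions
    distances = pd.Series(np.nan, index=ds.sample_ids, dtype=float)
    thresholds = {}
    flagged = pd.Series(False, index=ds.sample_ids)
    for cond, cols in ds.condition_groups().items():
        sub = X[cols].to_numpy()
        centroid = sub.mean(axis=1, keepdims=True)
        d = np.sqrt(((sub - centroid) ** 2).sum(axis=0))
        distances[cols] = d
        if len(cols) < 2:
            warnings.warn(
                f"group {cond!r} has a single sample; outlier detection skipped"
            )
            thresholds[cond] = np.inf
            continue
        q1, q3 = np.percentile(d, [25, 75])  # linear interpolation (type 7)
        thr = q3 + coef * (q3 - q1)
        thresholds[cond] = thr
        flagged[cols] = d > thr
    return OutlierReport(
        distances=distances,
        thresholds=pd.Series(thresholds, name="threshold"),
        flagged=flagged,
        groups=groups,
    )
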