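"""TMT batch-effect correction: internal reference scaling (IRS) and
linear-model batch removal (limBE), composable with any normalization.

IRS rescales each protein within each batch so that pooled-reference
channels (or the all-sample pseudo-reference when none are designated)
agree across batches — a multiplicative correction on raw scale.  limBE
fits, per protein, a least-squares model with condition effects and
sum-to-zero-coded batch effects and subtracts the fitted batch component,
leaving condition means untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ProteomicsDataset, Scale, to_log2, to_raw
from .normalize import NormalizationResult, normalize

__all__ = ["BatchDesign", "correct_irs", "correct_limbe", "apply_pipeline"]


@dataclass
class BatchDesign:
    """Batch/condition assignment and per-batch reference channels."""

    batch: pd.Series  # per sample
    condition: pd.Series  # per sample
    reference: pd.Series  # per sample, bool

    @classmethod
    def from_dataset(cls, ds: ProteomicsDataset) -> "BatchDesign":
        batches = ds.batches
        if batches.isna().any():
            missing = batches.index[batches.isna()].tolist()
            raise ValueError(f"samples without batch assignment: {missing}")
        return cls(batch=batches, condition=ds.conditions, reference=ds.reference_mask)

    @property
    def batch_levels(self) -> list[str]:
        return sorted(self.batch.unique())

    def reference_samples(self, batch: str) -> list[str]:
        in_batch = self.batch == batch
        refs = self.reference & in_batch
        if refs.any():
            return self.reference.index[refs].tolist()
        return self.batch.index[in_batch].tolist()  # all-sample fallback


def correct_irs(
    ds: ProteomicsDataset, design: BatchDesign | None = None
) -> NormalizationResult:
    """Internal reference scaling (raw scale, output log2).

    For each protein, the geometric mean of the batch's reference samples is
    scaled to the geometric mean of those references over batches; every
    observed value of the protein in that batch is multiplied by the same
    factor.  Proteins without an observed reference value in a batch stay
    uncorrected there (recorded in params).
    """
    if design is None:
        design = BatchDesign.from_dataset(ds)
    levels = design.batch_levels
    if len(levels) < 2:
        raise ValueError("IRS requires >= 2 batches")
    R = to_raw(ds).intensities.astype(float)
    logR = np.log2(R)  # geometric means are arithmetic means on log2
    ref_profiles = {}
    for b in levels:
        cols = design.reference_samples(b)
        ref_profiles[b] = logR[cols].mean(axis=1, skipna=True)
    ref = pd.DataFrame(ref_profiles)
    target = ref.mean(axis=1, skipna=True)
    out = logR.copy()
    uncorrected: dict[str, list] = {}
    for b in levels:
        cols = design.batch.index[design.batch == b]
        shift = target - ref[b]  # log2 of t_i / r_ib
        missing_ref = shift.isna()
        uncorrected[b] = ref.index[missing_ref & R[cols].notna().any(axis=1)].tolist()
        out[cols] = out[cols].add(shift.fillna(0.0), axis=0)
    return NormalizationResult(
        "irs",
        out,
        {"reference_profiles": ref, "target": target, "uncorrected": uncorrected},
    )


def _check_confounding(design: BatchDesign) -> None:
    """Error when batch and condition define the same sample partition or the
    joint design matrix is rank-deficient."""
    tab = pd.crosstab(design.batch, design.condition)
    # each batch maps to exactly one condition and vice versa -> confounded
    if (tab > 0).sum(axis=1).max() == 1 or (tab > 0).sum(axis=0).max() == 1:
        raise ValueError(
            "batch is confounded with condition: batch effects are not "
            "identifiable separately from condition effects"
        )


def correct_limbe(
    ds: ProteomicsDataset, design: BatchDesign | None = None
) -> NormalizationResult:
    """Linear-model batch-effect removal (log2 scale).

    Per protein, fits y = X beta + Z gamma with X = intercept + condition
    indicators (treatment coding) and Z = sum-to-zero-coded batch covariates,
    then returns y - Z gamma_hat.  The sum-to-zero coding guarantees that
    removing the batch component does not shift condition means.  Missing
    entries are skipped in the fit and preserved.
    """
    if design is None:
        design = BatchDesign.from_dataset(ds)
    if len(design.batch_levels) < 2:
        raise ValueError("limBE requires >= 2 batches")
    _check_confounding(design)
    X = to_log2(ds).intensities.astype(float)
    conds = pd.get_dummies(design.condition, drop_first=True, dtype=float)
    ones = np.ones((X.shape[1], 1))
    levels = design.batch_levels
    # sum-to-zero coding: last batch level = -1 on all columns
    Z = np.zeros((X.shape[1], len(levels) - 1))
    batch_codes = design.batch.map({b: i for i, b in enumerate(levels)}).to_numpy()
    for j in range(len(levels) - 1):
        Z[batch_codes == j, j] = 1.0
    Z[batch_codes == len(levels) - 1, :] = -1.0
    D = np.hstack([ones, conds.to_numpy(), Z])
    n_cond = 1 + conds.shape[1]
    V = X.to_numpy()
    out = V.copy()
    for i in range(V.shape[0]):
        obs = ~np.isnan(V[i])
        if obs.sum() <= D.shape[1]:
            d = D[obs]
            if np.linalg.matrix_rank(d) < d.shape[1]:
                continue  # not enough observations to separate effects
        beta, *_ = np.linalg.lstsq(D[obs], V[i, obs], rcond=None)
        out[i, obs] = V[i, obs] - D[obs][:, n_cond:] @ beta[n_cond:]
    return NormalizationResult(
        "limbe",
        pd.DataFrame(out, index=X.index, columns=X.columns),
        {"batch_levels": levels, "coding": "sum-to-zero"},
    )


def apply_pipeline(
    ds: ProteomicsDataset,
    method: str = "log2",
    be: str = "none",
    order: str = "be_last",
    method_kwargs: dict | None = None,
) -> NormalizationResult:
    """Compose a normalization method with a batch-effect correction.

    ``order="be_last"`` (default): normalize, then correct.  ``be_first``:
    correct, then normalize.  IRS operating on the log2 output of a
    normalization internally exponentiates (never fails on scale alone);
    the composition is recorded in ``params["composition"]``.
    """
    if be not in ("none", "irs", "limbe"):
        raise ValueError(f"unknown batch correction {be!r}")
    if order not in ("be_first", "be_last"):
        raise ValueError(f"unknown order {order!r}")
    method_kwargs = method_kwargs or {}
    if be == "none":
        res = normalize(ds, method, **method_kwargs)
        res.params["composition"] = [method]
        return res
    design = BatchDesign.from_dataset(ds)
    correct = correct_irs if be == "irs" else correct_limbe

    if order == "be_first":
        step1 = correct(ds, design)
        mid = ds.with_matrix(step1.matrix, scale=Scale.LOG2)
        res = normalize(mid, method, **method_kwargs)
        composition = [be, method]
        params = {"batch_correction": step1.params, "normalization": res.params}
    else:
        step1 = normalize(ds, method, **method_kwargs)
        mid = ds.with_matrix(step1.matrix, scale=Scale.LOG2)
        res = correct(mid, design)
        composition = [method, be]
        params = {"normalization": step1.params, "batch_correction": res.params}
    params["composition"] = composition
    return NormalizationResult(f"{method}+{be}", res.matrix, params)
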