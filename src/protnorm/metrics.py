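"""Evaluation metrics for normalization outputs.

Quantitative intragroup/intrabatch diagnostics:

* PMAD — pooled median absolute deviation: the mean, over proteins, of the
  within-group MAD.  Lower PMAD means tighter technical replicates.
* intragroup Pearson correlation of within-group sample pairs.
* silhouette coefficients S_j = (b_j - a_j)/max(a_j, b_j) on Euclidean
  distances over the first three principal components, computed per
  condition grouping (biological signal) or batch grouping (technical
  bias); a batch coefficient near 1 flags batch effects.
* average-linkage hierarchical clustering of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.metrics import silhouette_samples

__all__ = [
    "pmad",
    "pmad_reduction",
    "intragroup_pearson",
    "pca_embed",
    "silhouette_coefficients",
    "batch_condition_report",
    "hierarchical_clustering",
    "SilhouetteResult",
]

MAD_CONSTANT = 1.4826


def _group_map(groups: pd.Series | dict, columns) -> dict[str, list[str]]:
    if isinstance(groups, dict):
        return {g: list(cols) for g, cols in groups.items()}
    out: dict[str, list[str]] = {}
    for sample in columns:
        out.setdefault(groups[sample], []).append(sample)
    return out


def pmad(
    matrix_log2: pd.DataFrame,
    groups: pd.Series | dict,
    constant: float = MAD_CONSTANT,
) -> pd.Series:
    """Pooled median absolute deviation per sample group.

    PMAD_g = (sum_i MAD_ig) / n, with MAD_ig the median absolute deviation
    (times the consistency ``constant``) of protein i over group-g samples.
    Proteins with fewer than two observed group values are skipped (n is
    adjusted); a group of one sample is an error.
    """
    gm = _group_map(groups, matrix_log2.columns)
    out = {}
    for g, cols in gm.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = matrix_log2[cols]
        enough = sub.notna().sum(axis=1) >= 2
        sub = sub.loc[enough]
        med = sub.median(axis=1)
        mads = constant * (sub.sub(med, axis=0)).abs().median(axis=1)
        out[g] = float(mads.mean())
    return pd.Series(out, name="pmad")


def pmad_reduction(pmad_norm: pd.Series, pmad_log2: pd.Series) -> pd.Series:
    """Percent PMAD reduction vs the unnormalized log2 baseline:
    100 * (1 - PMAD_norm / PMAD_log2); negative values mean the method
    increased intragroup variation.  Zero baselines yield NaN."""
    base = pmad_log2.reindex(pmad_norm.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        red = 100.0 * (1.0 - pmad_norm / base)
    return red.mask(base == 0).rename("pmad_reduction_pct")


def intragroup_pearson(
    matrix_log2: pd.DataFrame, groups: pd.Series | dict, min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson r for every within-group sample pair.

    Returns a tidy frame (group, sample_1, sample_2, r); pairs sharing fewer
    than ``min_shared`` observed proteins are skipped with a warning.
    """
    gm = _group_map(groups, matrix_log2.columns)
    rows = []
    for g, cols in gm.items():
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                x = matrix_log2[cols[i]]
                y = matrix_log2[cols[j]]
                shared = x.notna() & y.notna()
                if shared.sum() < min_shared:
                    warnings.warn(
                        f"pair ({cols[i]}, {cols[j]}) shares fewer than "
                        f"{min_shared} observed proteins; skipped"
                    )
                    continue
                r = float(np.corrcoef(x[shared], y[shared])[0, 1])
                rows.append((g, cols[i], cols[j], r))
    return pd.DataFrame(rows, columns=["group", "sample_1", "sample_2", "r"])


def pca_embed(
    matrix_log2: pd.DataFrame, k: int = 3, scale_proteins: bool = False
) -> pd.DataFrame:
    """First-``k`` principal-component scores of the samples.

    PCA is computed on complete-case proteins with samples as observations
    and proteins centered (optionally scaled to unit variance).  Component
    signs follow a deterministic convention: the loading entry of largest
    magnitude is positive.
    """
    complete = matrix_log2.dropna(axis=0)
    if complete.shape[0] < k:
        raise ValueError(
            f"only {complete.shape[0]} complete proteins; need >= {k} for PCA"
        )
    X = complete.to_numpy().T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    if scale_proteins:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, S.size)
    scores = U[:, :k] * S[:k]
    for c in range(k):
        if Vt[c, np.argmax(np.abs(Vt[c]))] < 0:
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(
        scores, index=matrix_log2.columns, columns=[f"PC{i+1}" for i in range(k)]
    )


@dataclass
class SilhouetteResult:
    per_sample: pd.Series
    per_group: pd.Series
    overall: float


def silhouette_coefficients(
    embedding: pd.DataFrame, grouping: pd.Series | dict
) -> SilhouetteResult:
    """Silhouette coefficients S_j = (b_j - a_j)/max(a_j, b_j) on Euclidean
    distances over an embedding.

    a_j: mean distance of sample j to its own group (excluding itself);
    b_j: minimum over other groups of the mean distance to that group.
    Samples in singleton groups receive S_j = 0.
    """
    if isinstance(grouping, dict):
        inv = {s: g for g, cols in grouping.items() for s in cols}
        labels = pd.Series([inv[s] for s in embedding.index], index=embedding.index)
    else:
        labels = grouping.reindex(embedding.index)
    if labels.nunique() < 2:
        raise ValueError("silhouette requires >= 2 groups")
    values = silhouette_samples(embedding.to_numpy(), labels.to_numpy())
    per_sample = pd.Series(values, index=embedding.index, name="silhouette")
    per_group = per_sample.groupby(labels).mean()
    return SilhouetteResult(
        per_sample=per_sample, per_group=per_group, overall=float(per_sample.mean())
    )


def batch_condition_report(
    matrix_log2: pd.DataFrame,
    condition: pd.Series,
    batch: pd.Series,
    k: int = 3,
) -> dict[str, float]:
    """Overall mean silhouettes of the same 3-PC embedding under the batch
    grouping and under the condition grouping.

    A batch coefficient close to 1 indicates batch effects dominate the
    sample structure; a condition coefficient close to 1 indicates the
    biological signal dominates.
    """
    emb = pca_embed(matrix_log2, k=k)
    return {
        "batch_coefficient": silhouette_coefficients(emb, batch).overall,
        "condition_coefficient": silhouette_coefficients(emb, condition).overall,
    }


def hierarchical_clustering(
    matrix_log2: pd.DataFrame, linkage: str = "average"
) -> dict:
    """Agglomerative clustering of samples on Euclidean distances over
    complete-case proteins.

    Returns the scipy linkage matrix, the leaf order, and a ``cut(k)``
    helper mapping samples to cluster labels.  Ties are broken
    deterministically by sample index (scipy's stable ordering).
    """
    if matrix_log2.shape[1] < 3:
        raise ValueError("hierarchical clustering needs >= 3 samples")
    complete = matrix_log2.dropna(axis=0)
    D = ssd.pdist(complete.to_numpy().T, metric="euclidean")
    Z = sch.linkage(D, method=linkage)
    leaves = [matrix_log2.columns[i] for i in sch.leaves_list(Z)]
    samples = list(matrix_log2.columns)

    def cut(k: int) -> pd.Series:
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        return pd.Series(labels, index=samples, name="cluster")

    return {"linkage": Z, "leaf_order": leaves, "cut": cut}
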