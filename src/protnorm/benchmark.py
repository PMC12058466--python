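"""Scoring of normalization methods.

With spike-in ground truth: confusion metrics (a spike-in protein called DE
is a true positive, a background protein called DE is a false positive),
FPR, precision/recall/F1, rank-based AUC, and logFC accuracy against the
expected log2 concentration ratios.  Without ground truth: DE counts per
method, Jaccard intersection of DE sets, consensus sets, and method ranking
by median F1 with paired Wilcoxon signed-rank comparisons against the top
method.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import SpikeInTruth
from .de import DEResult

__all__ = [
    "ConfusionMetrics",
    "confusion_from_de",
    "roc_auc",
    "expected_logfc",
    "logfc_accuracy",
    "jaccard_matrix",
    "de_count_summary",
    "rank_methods",
    "score_method",
]


@dataclass
class ConfusionMetrics:
    """Confusion counts and derived rates for one DE result vs truth."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "FPR": self.fpr, "precision": self.precision,
            "recall": self.recall, "F1": self.f1, "AUC": self.auc,
        }


def confusion_from_de(de: DEResult, truth: SpikeInTruth) -> ConfusionMetrics:
    """Count TP/FP/TN/FN from DE calls against spike-in labels.

    Only proteins with a truth label are countable; a tested protein without
    one is an error.  Untestable proteins (NaN p) are counted as not-DE,
    i.e. spike-ins that could not be tested become false negatives.
    """
    tested = de.table.index
    missing = tested.difference(truth.label.index)
    if len(missing):
        raise ValueError(
            f"proteins without truth label: {missing.tolist()[:5]}"
        )
    labels = truth.label.reindex(tested)
    is_de = (de.table["call"] != "ns").to_numpy()
    spike = (labels == "spike_in").to_numpy()
    tp = int(np.sum(spike & is_de))
    fn = int(np.sum(spike & ~is_de))
    fp = int(np.sum(~spike & is_de))
    tn = int(np.sum(~spike & ~is_de))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_auc(scores: pd.Series, labels: pd.Series) -> float:
    """Rank-based AUC (Mann-Whitney U / (n+ * n-), half credit for ties).

    ``scores`` rank candidates (higher = more DE-like; use -log10 p);
    ``labels`` is the spike-in indicator.  Both classes must be present.
    """
    labels = labels.reindex(scores.index)
    y = (labels == "spike_in").to_numpy() if labels.dtype == object else labels.to_numpy(bool)
    s = scores.to_numpy(dtype=float)
    ok = ~np.isnan(s)  # +/-inf are legitimate extreme ranks
    y, s = y[ok], s[ok]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = scipy.stats.rankdata(s, method="average")
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def expected_logfc(truth: SpikeInTruth, case: str, control: str) -> pd.Series:
    """Expected log2 fold change per protein for a Case - Control contrast:
    log2(conc_case / conc_control) for spike-ins, 0 for background."""
    for cond in (case, control):
        if cond not in truth.concentration.columns:
            raise ValueError(f"no concentration defined for condition {cond!r}")
    out = pd.Series(0.0, index=truth.label.index, name="expected_logFC")
    spikes = truth.label == "spike_in"
    conc = truth.concentration.loc[spikes]
    out[spikes] = np.log2(conc[case] / conc[control])
    return out


def logfc_accuracy(
    de: DEResult, truth: SpikeInTruth, case: str, control: str
) -> dict[str, float]:
    """Median observed background logFC (target 0) and median spike-in bias
    (observed - expected)."""
    expected = expected_logfc(truth, case, control)
    obs = de.table["logFC"]
    bg = truth.background_ids.intersection(obs.index)
    sp = truth.spike_ids.intersection(obs.index)
    return {
        "background_median_logfc": float(obs.loc[bg].median()),
        "spikein_median_bias": float((obs.loc[sp] - expected.loc[sp]).median()),
    }


def jaccard_matrix(de_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise Jaccard similarity J(A,B) = |A & B| / |A | B| between named
    DE sets; J of two empty sets is defined as 1."""
    if len(de_sets) < 2:
        raise ValueError("need >= 2 DE sets")
    names = list(de_sets)
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        A, B = set(de_sets[a]), set(de_sets[b])
        union = A | B
        val = 1.0 if not union else len(A & B) / len(union)
        J.loc[a, b] = J.loc[b, a] = val
    return J


def de_count_summary(
    de_results: dict[str, DEResult], consensus_methods: list[str] | None = None
) -> tuple[pd.DataFrame, set]:
    """Up/down DE counts per method plus a consensus DE set.

    All results must refer to the same comparison.  The consensus set is the
    intersection of DE proteins over ``consensus_methods`` (default: all).
    """
    comparisons = {r.comparison for r in de_results.values()}
    if len(comparisons) > 1:
        raise ValueError(f"mismatched comparisons: {sorted(comparisons)}")
    rows = {}
    for name, res in de_results.items():
        calls = res.table["call"]
        rows[name] = {
            "up": int((calls == "up").sum()),
            "down": int((calls == "down").sum()),
            "total": int((calls != "ns").sum()),
        }
    counts = pd.DataFrame(rows).T
    methods = consensus_methods or list(de_results)
    consensus: set | None = None
    for m in methods:
        s = set(de_results[m].de_proteins)
        consensus = s if consensus is None else consensus & s
    return counts, consensus or set()


def rank_methods(f1_table: pd.DataFrame) -> pd.DataFrame:
    """Rank methods by median F1 and compare each to the top method.

    ``f1_table``: one row per (comparison/dataset) observation, one column
    per method.  Methods are ordered by median F1 descending; each is
    compared to the leader with a paired two-sided Wilcoxon signed-rank
    test (exact for n <= 25).  Rows with missing entries are dropped with a
    warning.
    """
    complete = f1_table.dropna(axis=0)
    if complete.shape[0] < f1_table.shape[0]:
        warnings.warn(
            f"dropped {f1_table.shape[0] - complete.shape[0]} unpaired rows"
        )
    medians = complete.median(axis=0).sort_values(ascending=False, kind="stable")
    top = medians.index[0]
    rows = []
    for rank, method in enumerate(medians.index, start=1):
        if method == top:
            p = np.nan
        else:
            x = complete[top].to_numpy()
            y = complete[method].to_numpy()
            if complete.shape[0] < 5:
                raise ValueError("need >= 5 paired observations for testing")
            if np.allclose(x, y):
                p = 1.0
            else:
                mode = "exact" if complete.shape[0] <= 25 else "approx"
                p = float(
                    scipy.stats.wilcoxon(
                        x, y, alternative="two-sided", mode=mode
                    ).pvalue
                )
        rows.append((rank, method, float(medians[method]), p))
    return pd.DataFrame(
        rows, columns=["rank", "method", "median_f1", "p_vs_top"]
    ).set_index("method")


def score_method(
    de: DEResult, truth: SpikeInTruth, case: str, control: str
) -> dict[str, float]:
    """One-stop spike-in scoring: confusion metrics + AUC + logFC accuracy.

    The AUC ranking score is -log10 of the raw p-value (monotone-equivalent
    to ranking by |moderated t| at fixed df).
    """
    cm = confusion_from_de(de, truth)
    with np.errstate(divide="ignore"):
        scores = -np.log10(de.table["p"])
    cm.auc = roc_auc(scores, truth.label)
    out = cm.as_dict()
    out.update(logfc_accuracy(de, truth, case, control))
    return out
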