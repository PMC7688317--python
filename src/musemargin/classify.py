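"""Patch-level ROC/Youden classification and evaluator statistics.

Invasive carcinoma carries a higher nuclear-to-cytoplasm ratio than normal
breast parenchyma, so the classification rule is "invasive iff N/C >= t".
The ROC curve sweeps t over the observed values, the area under the curve
equals the probability that a random invasive patch outscores a random
normal one (ties counting one half), and the Youden index J = max(sens +
spec - 1) picks the operating cutoff that weighs false positives and false
negatives equally.

Visual-evaluation performance is summarised from confusion matrices as
sensitivity / specificity / accuracy percentages, rounded half-up to two
decimals for reporting while full precision is kept internally; multiple
evaluators are combined by the unweighted mean of their percentages.

Group comparisons between tissue subtypes use a sample-level cluster
bootstrap: whole samples are resampled with replacement within each group,
respecting that patches from one sample are correlated, with Holm
adjustment across the pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "ConfusionMatrix",
    "EvaluatorStats",
    "roc_curve",
    "youden_cutoff",
    "confusion_stats",
    "average_evaluators",
    "cluster_compare",
]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RocResult:
    """ROC points, AUC and the Youden operating point."""

    thresholds: np.ndarray  # descending; leading sentinel above the max value
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    j: float
    sens_at_cutoff: float
    spec_at_cutoff: float


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts for invasive-vs-normal calls."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class EvaluatorStats:
    """Sensitivity / specificity / accuracy in percent (full precision)."""

    sensitivity: float
    specificity: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> "EvaluatorStats":
        return EvaluatorStats(
            sensitivity=_round_half_up(self.sensitivity, ndigits),
            specificity=_round_half_up(self.specificity, ndigits),
            accuracy=_round_half_up(self.accuracy, ndigits),
        )


def roc_curve(values, labels) -> RocResult:
    """ROC for the rule "invasive iff value >= threshold".

    ``labels`` are truthy for invasive (positive) patches.  Thresholds are
    the sorted unique values plus a sentinel above the maximum; the AUC is
    the trapezoid area, equal to the tie-aware pair-counting probability
    P(value_pos > value_neg) + 0.5 P(tie).  The Youden cutoff maximises
    sens + spec - 1 with ties broken toward the higher threshold (fewer
    false positives).
    """
    v = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), v, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j_all = tpr - fpr
    # thresholds are descending, so the first maximum is the highest cutoff
    idx = int(np.argmax(j_all))
    return RocResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        youden_threshold=float(thr[idx]),
        j=float(j_all[idx]),
        sens_at_cutoff=float(tpr[idx]),
        spec_at_cutoff=float(1.0 - fpr[idx]),
    )


def youden_cutoff(roc: RocResult) -> tuple[float, float, float, float]:
    """(threshold, J, sensitivity, specificity) at the Youden optimum."""
    j_all = roc.tpr - roc.fpr
    idx = int(np.argmax(j_all))
    return (
        float(roc.thresholds[idx]),
        float(j_all[idx]),
        float(roc.tpr[idx]),
        float(1.0 - roc.fpr[idx]),
    )


def confusion_stats(m: ConfusionMatrix) -> EvaluatorStats:
    """Sensitivity, specificity and accuracy (percent) from a 2x2 table."""
    pos = m.tp + m.fn
    neg = m.fp + m.tn
    if pos == 0 or neg == 0:
        raise ValueError(
            "sensitivity/specificity undefined: a class has zero samples"
        )
    return EvaluatorStats(
        sensitivity=100.0 * m.tp / pos,
        specificity=100.0 * m.tn / neg,
        accuracy=100.0 * (m.tp + m.tn) / (pos + neg),
    )


def average_evaluators(matrices: list[ConfusionMatrix]) -> EvaluatorStats:
    """Unweighted mean of per-evaluator percentages."""
    if not matrices:
        raise ValueError("need at least one confusion matrix")
    stats = [confusion_stats(m) for m in matrices]
    n = len(stats)
    return EvaluatorStats(
        sensitivity=sum(s.sensitivity for s in stats) / n,
        specificity=sum(s.specificity for s in stats) / n,
        accuracy=sum(s.accuracy for s in stats) / n,
    )


def cluster_compare(
    values,
    labels,
    sample_ids,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise group comparisons by sample-level cluster bootstrap.

    Patches from one physical sample are correlated, so the bootstrap
    resamples whole samples (clusters) with replacement within each group
    and recomputes the pooled group means.  For every pair of groups the
    observed difference in means, the percentile 95% confidence interval
    and a two-sided bootstrap p-value are reported, with Holm adjustment
    across the pairs.  Groups with a single sample yield an undefined CI
    (NaN) and are flagged.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable intervals")
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=np.float64),
            "group": np.asarray(labels),
            "sample": np.asarray(sample_ids),
        }
    )
    rng = np.random.default_rng(seed)
    groups = sorted(df["group"].unique().tolist())
    clusters: dict[str, list[np.ndarray]] = {}
    for g in groups:
        sub = df[df["group"] == g]
        clusters[g] = [
            sub.loc[sub["sample"] == s, "value"].to_numpy()
            for s in sorted(sub["sample"].unique().tolist())
        ]

    def pooled_mean(cluster_list: list[np.ndarray]) -> float:
        return float(np.concatenate(cluster_list).mean())

    boot_means = {}
    for g in groups:
        cl = clusters[g]
        k = len(cl)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, k, size=k)
            draws[b] = pooled_mean([cl[i] for i in pick])
        boot_means[g] = draws

    records = []
    for ga, gb in combinations(groups, 2):
        mean_a = pooled_mean(clusters[ga])
        mean_b = pooled_mean(clusters[gb])
        diff = mean_a - mean_b
        degenerate = len(clusters[ga]) < 2 or len(clusters[gb]) < 2
        boot_diff = boot_means[ga] - boot_means[gb]
        if degenerate:
            lo = hi = float("nan")
            p = float("nan")
        else:
            lo, hi = np.percentile(boot_diff, [2.5, 97.5])
            n_le = int((boot_diff <= 0).sum())
            n_ge = int((boot_diff >= 0).sum())
            p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
        records.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "diff": diff,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_value": p,
                "single_sample_group": degenerate,
            }
        )
    out = pd.DataFrame.from_records(records)
    # Holm step-down adjustment over the finite p-values
    finite = out["p_value"].notna()
    p = out.loc[finite, "p_value"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    out["p_holm"] = np.nan
    out.loc[finite, "p_holm"] = adj
    return out
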