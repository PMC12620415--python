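"""Nonparametric group comparison and diagnostic-performance statistics.

Implements the statistical stage applied to patient-level TAWSS: tie-corrected
Kruskal-Wallis H, Dunn's post hoc z tests with Bonferroni adjustment,
Spearman rank correlation, ROC analysis with the Mann-Whitney AUC identity,
Youden-J optimal cutoff selection, and 2x2 diagnostic metrics with Wilson
score 95% confidence intervals.

Orientation convention: for TAWSS, *lower* values indicate disease, so a
patient is predicted positive when the score falls *below* the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairwiseResult",
    "GroupComparison",
    "MetricCI",
    "RocResult",
    "kruskal_wallis",
    "dunn_test",
    "compare_groups",
    "spearman",
    "roc",
    "youden_cutoff",
    "confusion_metrics",
]


# ---------------------------------------------------------------------------
# rank-based group comparisons


def _pooled_midranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)  # midranks
    out = []
    start = 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    return ranks, out


def _tie_sum(pooled_ranks: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled_ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (every pooled value identical) returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ranks, group_ranks = _pooled_midranks(groups)
    n = len(ranks)
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in group_ranks
    )
    correction = 1.0 - _tie_sum(ranks) / (n**3 - n)
    if correction <= 0:  # all values tied
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


@dataclass
class PairwiseResult:
    pair: tuple[int, int]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    H: float
    p_global: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def dunn_test(groups: list[np.ndarray], adjustment: str = "bonferroni") -> list[PairwiseResult]:
    """Dunn's pairwise z tests on pooled midranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` over tie groups; two-sided normal p, Bonferroni
    multiplied by the number of pairs and capped at 1.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ranks, group_ranks = _pooled_midranks(groups)
    n = len(ranks)
    tie_term = _tie_sum(ranks) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = 0.0 if se == 0 else float((group_ranks[i].mean() - group_ranks[j].mean()) / se)
            p_raw = float(2.0 * stats.norm.sf(abs(z)))
            p_adj = min(1.0, n_pairs * p_raw) if adjustment == "bonferroni" else p_raw
            results.append(PairwiseResult(pair=(i, j), z=z, p_raw=p_raw, p_adjusted=p_adj))
    return results


def compare_groups(groups: list[np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis followed by Dunn-Bonferroni post hoc tests."""
    h, p = kruskal_wallis(groups)
    return GroupComparison(H=h, p_global=p, pairwise=dunn_test(groups))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-safe Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# ROC / diagnostic performance


@dataclass
class MetricCI:
    """A proportion with its Wilson score 95% CI; value is NaN and the CI
    absent when the denominator is empty."""

    value: float
    ci_low: float | None
    ci_high: float | None


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    AUC: float
    optimal_cutoff: float
    J_max: float
    confusion: dict[str, int]
    metrics: dict[str, MetricCI]
    orientation: str = "lower"


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def _wilson(successes: int, total: int) -> MetricCI:
    if total == 0:
        return MetricCI(value=float("nan"), ci_low=None, ci_high=None)
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return MetricCI(value=successes / total, ci_low=float(lo), ci_high=float(hi))


def confusion_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    orientation: str = "lower",
) -> tuple[dict[str, int], dict[str, MetricCI]]:
    """2x2 table and sens/spec/PPV/NPV (Wilson 95% CIs) at a threshold.

    With ``orientation="lower"`` a case is predicted positive when
    ``score < threshold``; with ``"higher"`` when ``score > threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if orientation == "lower":
        pred = scores < threshold
    elif orientation == "higher":
        pred = scores > threshold
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    confusion = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    metrics = {
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "PPV": _wilson(tp, tp + fp),
        "NPV": _wilson(tn, tn + fn),
    }
    return confusion, metrics


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray, orientation: str) -> float:
    """AUC as the probability a positive scores on the diseased side of a
    negative (ties count one half)."""
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    if orientation == "lower":
        wins = np.sum(diff < 0) + 0.5 * np.sum(diff == 0)
    else:
        wins = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(wins / (len(pos) * len(neg)))


def roc(scores: np.ndarray, labels: np.ndarray, orientation: str = "lower") -> RocResult:
    """Full ROC analysis of a continuous score against binary labels.

    Thresholds are the midpoints between adjacent distinct scores, bracketed
    by -inf and +inf sentinels; AUC uses the Mann-Whitney identity (equal to
    the trapezoidal area under the empirical curve). The optimal cutoff
    maximizes Youden's J = sensitivity + specificity - 1, ties broken toward
    higher specificity, then lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if orientation not in ("lower", "higher"):
        raise ValueError(f"unknown orientation {orientation!r}")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = scores < thr if orientation == "lower" else scores > thr
        sens[i] = np.sum(pred & labels) / n_pos
        spec[i] = np.sum(~pred & ~labels) / n_neg

    auc = _mann_whitney_auc(scores, labels, orientation)

    j = sens + spec - 1.0
    j_max = float(np.max(j))
    best = np.flatnonzero(j >= j_max - 1e-12)
    # tie-break: higher specificity, then lower threshold
    best = best[np.lexsort((thresholds[best], -spec[best]))]
    cutoff = float(thresholds[best[0]])

    confusion, metrics = confusion_metrics(scores, labels, cutoff, orientation)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        AUC=auc,
        optimal_cutoff=cutoff,
        J_max=j_max,
        confusion=confusion,
        metrics=metrics,
        orientation=orientation,
    )


def youden_cutoff(roc_result: RocResult) -> tuple[float, float]:
    """(optimal_cutoff, J_max) from a computed :class:`RocResult`."""
    return roc_result.optimal_cutoff, roc_result.J_max
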