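"""Binary-classification metrics and the Hanley–McNeil AUC comparison.

Thresholded metrics (sensitivity, specificity, precision, MCC) use a 0.5
cutoff with ties predicted positive.  AUC is the Mann–Whitney statistic
with midrank tie handling; AUPRC is the average-precision sweep with tied
scores grouped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "sensitivity",
    "specificity",
    "precision",
    "mcc",
    "auc",
    "auprc",
    "evaluate",
    "cv_average",
    "hanley_mcneil_se",
    "hanley_mcneil_test",
    "HanleyMcNeilResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_labels_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary")
    return y.astype(int), s


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion table; score >= threshold predicts case."""
    y, s = _as_labels_scores(labels, scores)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 by convention when any denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom))


def _check_two_classes(y: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def auc(labels, scores) -> float:
    """P(random case outscores random control), ties counting 1/2.

    Computed from midranks (Mann–Whitney U), equivalent to trapezoidal ROC
    integration.
    """
    y, s = _as_labels_scores(labels, scores)
    n_pos, n_neg = _check_two_classes(y)
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auprc(labels, scores) -> float:
    """Average precision over a descending-score sweep, tied scores grouped."""
    y, s = _as_labels_scores(labels, scores)
    n_pos, _ = _check_two_classes(y)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # group boundaries where the score value changes
    boundaries = np.nonzero(np.diff(s_sorted))[0]
    group_ends = np.concatenate([boundaries, [y.size - 1]])
    tp_cum = np.cumsum(y_sorted)[group_ends]
    n_cum = group_ends + 1.0
    prec = tp_cum / n_cum
    delta_tp = np.diff(np.concatenate([[0], tp_cum]))
    return float(np.sum(prec * delta_tp) / n_pos)


@dataclass(frozen=True)
class MetricsReport:
    """The six reported metrics on the [0, 1] / [-1, 1] scale, plus class sizes."""

    sen: float
    spe: float
    pre: float
    mcc: float
    auc: float
    auprc: float
    n_pos: int
    n_neg: int

    FIELDS = ("sen", "spe", "pre", "mcc", "auc", "auprc")

    def as_row(self, scale: float = 100.0) -> dict[str, float]:
        """Table row on the paper's x100 scale."""
        return {k.capitalize(): scale * getattr(self, k) for k in self.FIELDS}


def evaluate(labels, scores, threshold: float = 0.5) -> MetricsReport:
    y, s = _as_labels_scores(labels, scores)
    n_pos, n_neg = _check_two_classes(y)
    c = confusion(y, s, threshold)
    return MetricsReport(
        sen=sensitivity(c),
        spe=specificity(c),
        pre=precision(c),
        mcc=mcc(c),
        auc=auc(y, s),
        auprc=auprc(y, s),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def bce_of_scores(labels, scores, eps: float = 1e-12) -> float:
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(scores, dtype=float), eps, 1 - eps)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def cv_average(reports: Sequence[MetricsReport]) -> tuple[MetricsReport, dict[str, float]]:
    """Unweighted per-metric mean and (population) std over folds."""
    if not reports:
        raise ValueError("need at least one fold")
    means = {}
    stds = {}
    for k in MetricsReport.FIELDS:
        vals = np.array([getattr(r, k) for r in reports])
        means[k] = float(vals.mean())
        stds[k] = float(vals.std())
    mean_report = MetricsReport(
        **means,
        n_pos=int(sum(r.n_pos for r in reports)),
        n_neg=int(sum(r.n_neg for r in reports)),
    )
    return mean_report, stds


def hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUC estimate per the Hanley–McNeil formula."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


class HanleyMcNeilResult(NamedTuple):
    z: float
    p: float
    auc_a: float
    auc_b: float
    se_a: float
    se_b: float


def hanley_mcneil_test(
    labels, scores_a, scores_b, r: float = 0.0
) -> HanleyMcNeilResult:
    """Two-sided z-test for a difference between two AUCs on the same labels.

    ``r`` is the correlation between the two AUC estimates; the default 0
    gives the conservative independent-areas approximation.  Degenerate AUCs
    (0 or 1) get an SE floor of 1/(n_pos * n_neg) with a warning.
    """
    y, sa = _as_labels_scores(labels, scores_a)
    _, sb = _as_labels_scores(labels, scores_b)
    n_pos, n_neg = _check_two_classes(y)
    a1, a2 = auc(y, sa), auc(y, sb)
    floor = 1.0 / (n_pos * n_neg)
    se1, se2 = hanley_mcneil_se(a1, n_pos, n_neg), hanley_mcneil_se(a2, n_pos, n_neg)
    if se1 == 0.0 or se2 == 0.0:
        warnings.warn("degenerate AUC: applying SE floor", stacklevel=2)
        se1, se2 = max(se1, floor), max(se2, floor)
    var_diff = se1**2 + se2**2 - 2.0 * r * se1 * se2
    if a1 == a2:
        z = 0.0
    else:
        z = (a1 - a2) / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return HanleyMcNeilResult(float(z), p, a1, a2, se1, se2)
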