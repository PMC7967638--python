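"""Classification and ROC evaluation of an integer risk score.

A record is classified positive when its score is at or above the cutoff,
so cutoff 0 classifies everyone positive (sensitivity 100%, specificity
0%).  The AUC is the Mann-Whitney probability that a random case outranks
a random non-case (ties count one half); its confidence interval uses the
DeLong structural-components variance with a normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["ClassificationRow", "RocResult", "classification_table", "auc",
           "select_cutoff"]


def _round1(x: float) -> float:
    """Round half-up to one decimal, for display parity with clinical tables."""
    return math.floor(x * 10 + 0.5) / 10


@dataclass(frozen=True)
class ClassificationRow:
    """One cutoff's classification percentages (raw fractions retained)."""

    cutoff: int
    sensitivity: float
    specificity: float
    correct_classification: float
    ppv: float | None  # None when no one is classified positive
    npv: float | None

    def display(self) -> dict[str, object]:
        out: dict[str, object] = {"cutoff": self.cutoff}
        for name in ("sensitivity", "specificity", "correct_classification"):
            out[name] = _round1(getattr(self, name))
        out["ppv"] = "" if self.ppv is None else _round1(self.ppv)
        out["npv"] = "" if self.npv is None else _round1(self.npv)
        return out


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int


def _check_labels(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one positive and one negative label")
    return s, y


def classification_table(
    scores: Sequence[int], labels: Sequence[int]
) -> list[ClassificationRow]:
    """Per-cutoff sensitivity/specificity/accuracy/PPV/NPV percentages.

    One row per observed score value plus a row just beyond the maximum
    (the classify-nobody cutoff); percentages are exact fractions times
    100, with undefined predictive values reported as None to mirror the
    blank cells of clinical classification tables.
    """
    s, y = _check_labels(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    cutoffs = sorted(set(int(v) for v in s)) + [int(s.max()) + 1]
    rows = []
    for c in cutoffs:
        pred = s >= c
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = n_neg - fp
        fn = n_pos - tp
        rows.append(
            ClassificationRow(
                cutoff=c,
                sensitivity=100.0 * tp / n_pos,
                specificity=100.0 * tn / n_neg,
                correct_classification=100.0 * (tp + tn) / (n_pos + n_neg),
                ppv=None if tp + fp == 0 else 100.0 * tp / (tp + fp),
                npv=None if tn + fn == 0 else 100.0 * tn / (tn + fn),
            )
        )
    return rows


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    sorted_x = x[order]
    while i < x.size:
        j = i
        while j < x.size and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def auc(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> RocResult:
    """Mann-Whitney AUC with a DeLong confidence interval.

    The point estimate is the tie-adjusted probability of correct
    ranking; the variance combines the empirical variances of the DeLong
    structural components (per-case and per-non-case placement values),
    and the normal-approximation interval is truncated to [0, 1].
    """
    s, y = _check_labels(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    # Placement values: v10[i] = P_hat(neg < pos_i) + P_hat(neg == pos_i)/2.
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    estimate = float(v10.mean())
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return RocResult(
        auc=estimate,
        auc_ci=(max(0.0, estimate - half), min(1.0, estimate + half)),
        n_pos=m,
        n_neg=n,
    )


def select_cutoff(
    table: Sequence[ClassificationRow],
    criterion: Literal["youden", "accuracy"] = "youden",
) -> int:
    """Cutoff maximizing Youden's J (default) or overall accuracy.

    Ties break toward the smaller cutoff, preferring sensitivity.
    """
    if not table:
        raise ValueError("empty classification table")
    if criterion == "youden":
        key = lambda r: r.sensitivity + r.specificity - 100.0
    elif criterion == "accuracy":
        key = lambda r: r.correct_classification
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = max(sorted(table, key=lambda r: r.cutoff), key=key)
    # max() keeps the first of equal keys after the sort, i.e. the smallest cutoff
    return best.cutoff
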