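"""Hindcast scoring and comparative statistics.

Predictions are confronted with pollen-derived presence grids on data cells
only; skill is summarised by the Sorensen index (2TP/(2TP+FP+FN), immune to
true-negative inflation) and the true skill statistic, transferability is the
relative change against reference-period performance, and groups of
performance values are compared with Kruskal-Wallis followed by pairwise
Conover-Iman post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st

from .pollen import NO_DATA, PRESENT, PresenceGrid

__all__ = [
    "ConfusionMatrix",
    "EmptyEvaluationError",
    "confusion",
    "sorensen_index",
    "tss",
    "transferability",
    "kruskal_wallis",
    "conover_iman",
]


class EmptyEvaluationError(ValueError):
    """Raised when an evaluation has no usable cells."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, obs: PresenceGrid) -> ConfusionMatrix:
    """Count the confusion matrix over cells with observed data only."""
    pred = np.asarray(pred, dtype=bool)
    if pred.shape != obs.state.shape:
        raise ValueError("prediction and observation grids are misaligned")
    mask = obs.state != NO_DATA
    if not mask.any():
        raise EmptyEvaluationError("no cells with presence/absence data")
    o = obs.state[mask] == PRESENT
    p = pred[mask]
    return ConfusionMatrix(
        tp=int(np.sum(p & o)), fp=int(np.sum(p & ~o)),
        fn=int(np.sum(~p & o)), tn=int(np.sum(~p & ~o)),
    )


def sorensen_index(cm: ConfusionMatrix) -> float:
    """Sorensen similarity 2TP/(2TP+FP+FN); true negatives never enter."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise EmptyEvaluationError("Sorensen index undefined: tp=fp=fn=0")
    return 2.0 * cm.tp / denom


def tss(cm: ConfusionMatrix) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise EmptyEvaluationError("TSS undefined: a confusion-matrix margin is zero")
    return cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp) - 1.0


def transferability(perf_bin: float, perf_reference: float) -> float:
    """Relative performance change against the reference period.

    Negative values mean performance is lower in the hindcast period than in
    the reference period.
    """
    if perf_reference == 0:
        raise ValueError("reference performance is zero; transferability undefined")
    return (perf_bin - perf_reference) / perf_reference


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All observations identical across groups gives (H=0, p=1) rather than an
    error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = st.kruskal(*groups)
    return float(h), float(p)


def conover_iman(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Conover-Iman post hoc tests on the Kruskal-Wallis ranks.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))
    with pooled rank variance S^2 and the tie-corrected H, referred to a
    Student-t with N-k degrees of freedom.  The sign convention is
    first-listed group minus second; p-values are two-sided and unadjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    h, _ = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    k = len(groups)
    ranks = st.rankdata(pooled)
    sizes = [len(g) for g in groups]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    rbar = [r.mean() for r in split]
    s2 = (np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0) / (n - 1.0)
    factor = s2 * (n - 1.0 - h) / (n - k)
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        t = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
        p = 2.0 * st.t.sf(abs(t), n - k) if se > 0 else 1.0
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "t": float(t), "p": float(min(p, 1.0))})
    return pd.DataFrame(rows)
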