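"""Exact and rank statistics for the cohort's clinicopathological claims.

Wraps the standard tests — Fisher's exact test on 2x2 tables (two-sided by
minimum-likelihood summation), pairwise mutation co-occurrence / mutual
exclusivity, the Mann-Whitney U test, Pearson/Spearman correlation — and
ROC analysis with Youden-J cut-point optimisation, behind small result
types that keep effect sizes next to p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "ContingencyTable",
    "TestResult",
    "MarkerEval",
    "fisher_exact",
    "pairwise_cooccurrence",
    "mann_whitney_u",
    "correlation",
    "roc_auc",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are groups, columns outcomes.

    Layout::

            outcome+  outcome-
      row1     a         b
      row2     c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table must contain at least one count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio ad/bc; inf and nan allowed on zero margins."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    effect: Optional[float] = None
    effect_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_two_sided}")


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric point probabilities no larger than
    the observed table's (minimum-likelihood convention, the dominant
    statistical-package behaviour). The reported effect is the sample odds
    ratio ad/bc. Degenerate tables with an empty margin give p = 1.
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return TestResult(statistic=math.nan, p_two_sided=1.0,
                          effect=table.odds_ratio, effect_name="odds_ratio")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=table.odds_ratio,
        p_two_sided=float(min(p, 1.0)),
        effect=table.odds_ratio,
        effect_name="odds_ratio",
    )


def pairwise_cooccurrence(
    mutation_matrix: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """Fisher co-occurrence / mutual-exclusivity tests for all gene pairs.

    ``mutation_matrix`` is a boolean cases x genes frame of pathogenic /
    likely-pathogenic mutation calls. For each unordered pair the 2x2 table
    of joint presence is tested; direction is "co-occurrence" when the
    sample odds ratio exceeds 1 and "exclusivity" when below. Raw p-values
    are reported; ``adjust=True`` adds a Benjamini-Hochberg column.
    """
    mat = mutation_matrix.astype(bool)
    rows = []
    for g1, g2 in itertools.combinations(mat.columns, 2):
        x, y = mat[g1].to_numpy(), mat[g2].to_numpy()
        tab = ContingencyTable(
            a=int(np.sum(x & y)),
            b=int(np.sum(x & ~y)),
            c=int(np.sum(~x & y)),
            d=int(np.sum(~x & ~y)),
        )
        if x.all() or (~x).all() or y.all() or (~y).all():
            rows.append((g1, g2, tab.a, math.nan, 1.0, "undefined"))
            continue
        res = fisher_exact(tab)
        if math.isnan(res.effect):
            direction = "undefined"
        elif res.effect > 1:
            direction = "co-occurrence"
        elif res.effect < 1:
            direction = "exclusivity"
        else:
            direction = "independent"
        rows.append((g1, g2, tab.a, res.effect, res.p_two_sided, direction))
    out = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_both", "odds_ratio", "p", "direction"]
    )
    if adjust and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample is small (n_x + n_y <= 12)
    and tie-free; otherwise the normal approximation with tie and
    continuity corrections. Effect is the rank-biserial correlation
    ``2 U / (n_x n_y) - 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u = float(res.statistic)
    rank_biserial = 2.0 * u / (x.size * y.size) - 1.0
    return TestResult(
        statistic=u,
        p_two_sided=float(min(res.pvalue, 1.0)),
        effect=rank_biserial,
        effect_name="rank_biserial",
    )


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> TestResult:
    """Pearson or Spearman correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance sample")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(r), p_two_sided=float(p),
                      effect=float(r), effect_name=method)


@dataclass(frozen=True)
class MarkerEval:
    """ROC evaluation of a diagnostic marker with a Youden-optimal cut."""

    roc_points: tuple[tuple[float, float], ...]  # (fpr, tpr)
    auc: float
    cutpoint: float
    youden_j: float
    sensitivity: float
    specificity: float
    accuracy: float


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> MarkerEval:
    """ROC curve, trapezoidal AUC, and the Youden-J optimal cut-point.

    The decision rule is "score >= cutpoint -> positive". Among thresholds
    tied for the maximum J = sensitivity + specificity - 1, the smallest is
    chosen (maximising sensitivity). Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be represented")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # skip the sentinel threshold (inf) that anchors the curve at (0, 0)
    finite = np.isfinite(thresholds)
    j = tpr[finite] - fpr[finite]
    jmax = j.max()
    candidates = thresholds[finite][np.isclose(j, jmax)]
    cutpoint = float(candidates.min())
    pred = scores >= cutpoint
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    sens = tp / labels.sum()
    spec = tn / (~labels).sum()
    return MarkerEval(
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        cutpoint=cutpoint,
        youden_j=float(sens + spec - 1.0),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float((tp + tn) / labels.size),
    )
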