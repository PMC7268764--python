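"""Validation statistics for angle grading.

Confusion matrix and correct rates, weighted kappa (quadratic by default,
linear available), the empirical Mann–Whitney ROC AUC for pairwise group
comparisons, one-way ANOVA for group separation, and Bland–Altman limits of
agreement for repeatability.

Quadratic weights are the package default for kappa because they reproduce
the chance-corrected agreement conventionally reported for ordinal grading
scales, giving partial credit proportional to 1 - (distance/(k-1))^2; the
linear weighting is exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import Grade

__all__ = [
    "ConfusionMatrix3",
    "AgreementResult",
    "BlandAltmanResult",
    "DegenerateMarginsError",
    "confusion_and_rates",
    "weighted_kappa",
    "empirical_auc",
    "one_way_anova",
    "pairwise_welch",
    "bland_altman",
    "pairwise_auc_table",
]

_GRADES = (Grade.SA, Grade.MA, Grade.LA)


class DegenerateMarginsError(ValueError):
    """Chance agreement is 1: kappa undefined."""


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts, rows = actual grade, columns = predicted, order SA/MA/LA."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if np.any(c < 0) or not np.all(c == np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if c.sum() <= 0:
            raise ValueError("confusion matrix is empty")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_labels(cls, actual: Sequence, predicted: Sequence
                    ) -> "ConfusionMatrix3":
        a = [Grade(x) if not isinstance(x, Grade) else x for x in actual]
        p = [Grade(x) if not isinstance(x, Grade) else x for x in predicted]
        if len(a) != len(p):
            raise ValueError("actual and predicted lengths differ")
        if len(a) == 0:
            raise ValueError("need at least one pair of labels")
        c = np.zeros((3, 3), dtype=np.int64)
        for ai, pi in zip(a, p):
            c[int(ai), int(pi)] += 1
        return cls(c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementResult:
    """Correct rates (and optionally weighted kappa) of a grading comparison."""

    overall_correct_rate: float
    per_class_rate: dict[Grade, float]
    kappa_w: float | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, SD and 1.96-SD limits of agreement for paired data."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float

    def __post_init__(self):
        if self.loa_low > self.loa_high:
            raise ValueError("loa_low must not exceed loa_high")


def confusion_and_rates(actual: Sequence, predicted: Sequence
                        ) -> tuple[ConfusionMatrix3, AgreementResult]:
    """Tabulate grades and compute overall and per-class correct rates.

    The overall rate is trace/total; the per-class rate is the diagonal cell
    over its row sum (NaN for an unobserved actual grade).
    """
    m = ConfusionMatrix3.from_labels(actual, predicted)
    c = m.counts.astype(float)
    overall = float(np.trace(c) / c.sum())
    rows = c.sum(axis=1)
    per = {}
    for g in _GRADES:
        per[g] = float(c[g, g] / rows[g]) if rows[g] > 0 else float("nan")
    return m, AgreementResult(overall_correct_rate=overall, per_class_rate=per)


def weighted_kappa(m: ConfusionMatrix3,
                   weights: Literal["quadratic", "linear"] = "quadratic"
                   ) -> float:
    """Two-rater weighted kappa on a 3x3 grading confusion matrix.

    kappa_w = (Po_w - Pe_w) / (1 - Pe_w) with agreement weights
    w_ij = 1 - ((i-j)/(k-1))^2 (quadratic, default) or 1 - |i-j|/(k-1)
    (linear).
    """
    k = 3
    i, j = np.indices((k, k))
    if weights == "quadratic":
        w = 1.0 - ((i - j) / (k - 1)) ** 2
    elif weights == "linear":
        w = 1.0 - np.abs(i - j) / (k - 1)
    else:
        raise ValueError("weights must be 'quadratic' or 'linear'")
    p = m.counts / m.total
    po = float((w * p).sum())
    pe = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    if 1.0 - pe < 1e-12:
        raise DegenerateMarginsError("degenerate margins: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def empirical_auc(scores_narrow: Sequence[float],
                  scores_wide: Sequence[float]) -> float:
    """Mann–Whitney AUC between a narrower and a wider grade group.

    Estimates P(narrow < wide) with half credit for ties, so values above 0.5
    mean a smaller parameter indicates a narrower angle.  Equivalent to the
    normalized rank-sum statistic.
    """
    a = np.asarray(scores_narrow, dtype=float)
    b = np.asarray(scores_wide, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_wide = ranks[len(a):].sum()
    u_wide = r_wide - len(b) * (len(b) + 1) / 2.0
    return float(u_wide / (len(a) * len(b)))


def one_way_anova(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: F with (k-1, N-k) df and P.

    Zero within-group variance with unequal means gives an infinite F; the P
    value is then floored at 1e-300 rather than reported as exactly 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least two observations")
    f, p = stats.f_oneway(*gs)
    f = float(f)
    p = float(p)
    if not np.isfinite(f):
        return float("inf"), 1e-300
    return f, max(p, 0.0)


def pairwise_welch(groups: Mapping[str, Sequence[float]],
                   bonferroni: bool = False) -> dict[tuple[str, str], float]:
    """Welch two-sample t-test P values for every group pair.

    ``bonferroni=True`` multiplies each P by the number of comparisons
    (capped at 1).
    """
    names = list(groups)
    out: dict[tuple[str, str], float] = {}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        p = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        if bonferroni:
            p = min(1.0, p * len(pairs))
        out[(a, b)] = p
    return out


def bland_altman(m1: Sequence[float], m2: Sequence[float] | None = None
                 ) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired measurement series.

    Accepts either two equal-length series or a single sequence of
    ``(measure1, measure2)`` pairs.  Limits of agreement are
    mean difference ± 1.96 SD.
    """
    if m2 is None:
        arr = np.asarray(m1, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) sequence")
        d = arr[:, 0] - arr[:, 1]
    else:
        a = np.asarray(m1, dtype=float)
        b = np.asarray(m2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired series must have equal length")
        d = a - b
    if len(d) < 2:
        raise ValueError("insufficient pairs: need at least 2")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd, loa_low=lo,
                             loa_high=hi, pct_within_loa=100.0 * within)


def pairwise_auc_table(values, grades: Sequence) -> "pd.DataFrame":
    """AUC of each parameter column for SA-vs-MA and MA-vs-LA comparisons.

    ``values`` is a DataFrame of parameter columns; ``grades`` the matching
    grade labels.  Rows of the result are the comparisons, columns the
    parameters.
    """
    import pandas as pd

    g = np.asarray([int(Grade(x)) for x in grades])
    rows = {}
    for name, (lo, hi) in {"SA vs MA": (Grade.SA, Grade.MA),
                           "MA vs LA": (Grade.MA, Grade.LA)}.items():
        row = {}
        for col in values.columns:
            v = np.asarray(values[col], dtype=float)
            row[col] = empirical_auc(v[g == int(lo)], v[g == int(hi)])
        rows[name] = row
    return pd.DataFrame(rows).T
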