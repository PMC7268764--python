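"""Proportional-odds (cumulative logit) grading of anterior chamber angles.

Angle sections/quadrants are graded small (SA), moderate (MA) or large (LA),
the ordinal collapse of Scheie gonioscopic grades (III–IV / II / open+I).
The grading model is a proportional-odds logistic regression on one or more
angle parameters X:

    Q_SA      = logit(P_SA)        = alpha1 - sum_i beta_i * X_i
    Q_SA+MA   = logit(P_SA + P_MA) = alpha2 - sum_i beta_i * X_i

with P_SA = expit(Q_SA), P_MA = expit(Q_SA+MA) - P_SA, P_LA the remainder.
Note the minus-sign convention: a *positive* beta means larger parameter
values push toward larger (wider) grades.  The shipped reference model uses
LID alone with alpha1 = -2.111, alpha2 = 0.019, beta_LID = 10.231.

Fitting is maximum likelihood via quasi-Newton (BFGS) with an analytic
gradient on the reparameterized thresholds alpha2 = alpha1 + exp(delta),
multi-start to guard against flat regions.  Standard errors come from the
inverse observed information at the optimum.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2

__all__ = [
    "Grade",
    "GonioscopyGrade",
    "OrderedLogitParams",
    "GradeProbabilities",
    "OrderedLogitFit",
    "BinaryLogitFit",
    "StepwiseResult",
    "ModelError",
    "UnknownPredictorError",
    "NonFiniteMLEError",
    "DegenerateLabelsError",
    "scheie_to_group",
    "scheie_to_open_closed",
    "reference_lid_model",
    "predict_probabilities",
    "classify",
    "fit_ordered_logit",
    "fit_binary_logit",
    "stepwise_select",
]


class Grade(enum.IntEnum):
    """Ordinal angle grade, SA < MA < LA."""

    SA = 0
    MA = 1
    LA = 2


class GonioscopyGrade(str, enum.Enum):
    """Scheie gonioscopic grade (open, then I–IV, narrowing)."""

    OPEN = "open"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


_SCHEIE_TO_GRADE = {
    GonioscopyGrade.OPEN: Grade.LA,
    GonioscopyGrade.I: Grade.LA,
    GonioscopyGrade.II: Grade.MA,
    GonioscopyGrade.III: Grade.SA,
    GonioscopyGrade.IV: Grade.SA,
}


class ModelError(ValueError):
    pass


class UnknownPredictorError(ModelError):
    pass


class NonFiniteMLEError(ModelError):
    """Likelihood has no finite maximum (complete separation)."""


class DegenerateLabelsError(ModelError):
    """At least one grade has no observations."""


def scheie_to_group(g: GonioscopyGrade | str) -> Grade:
    """Collapse a Scheie grade into the three-level angle grade.

    open, I -> LA; II -> MA; III, IV -> SA.
    """
    g = GonioscopyGrade(g)
    return _SCHEIE_TO_GRADE[g]


def scheie_to_open_closed(g: GonioscopyGrade | str) -> bool:
    """True when the angle counts as open (open, I, II); False for III/IV."""
    g = GonioscopyGrade(g)
    return g in (GonioscopyGrade.OPEN, GonioscopyGrade.I, GonioscopyGrade.II)


@dataclass(frozen=True)
class OrderedLogitParams:
    """Intercepts and named coefficients of the proportional-odds model."""

    alpha1: float
    alpha2: float
    beta: Mapping[str, float]

    def __post_init__(self):
        if not (self.alpha1 < self.alpha2):
            raise ValueError("thresholds must satisfy alpha1 < alpha2")
        object.__setattr__(self, "beta", dict(self.beta))

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.beta)

    def to_dict(self) -> dict:
        return {"alpha1": self.alpha1, "alpha2": self.alpha2,
                "beta": dict(self.beta)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "OrderedLogitParams":
        return cls(alpha1=float(d["alpha1"]), alpha2=float(d["alpha2"]),
                   beta={k: float(v) for k, v in d["beta"].items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "OrderedLogitParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reference_lid_model() -> OrderedLogitParams:
    """The built-in LID grading model shipped with the package."""
    text = resources.files("acangle.assets").joinpath(
        "lid_reference_2020.json").read_text()
    return OrderedLogitParams.from_dict(json.loads(text))


@dataclass(frozen=True)
class GradeProbabilities:
    """Cumulative logits and grade probabilities for one observation."""

    q_sa: float
    q_sa_ma: float
    p_sa: float
    p_ma: float
    p_la: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_sa, self.p_ma, self.p_la])


def predict_probabilities(params: OrderedLogitParams,
                          x: Mapping[str, float]) -> GradeProbabilities:
    """Grade probabilities for one predictor vector.

    Predictor names must match the model's coefficients exactly.
    """
    if set(x) != set(params.beta):
        unknown = set(x) ^ set(params.beta)
        raise UnknownPredictorError(
            f"unknown predictor(s) or missing predictor(s): {sorted(unknown)}")
    eta = sum(params.beta[k] * float(x[k]) for k in params.beta)
    q_sa = params.alpha1 - eta
    q_sa_ma = params.alpha2 - eta
    p_sa = float(expit(q_sa))
    p_cum = float(expit(q_sa_ma))
    return GradeProbabilities(q_sa=q_sa, q_sa_ma=q_sa_ma,
                              p_sa=p_sa, p_ma=p_cum - p_sa, p_la=1.0 - p_cum)


def classify(p: GradeProbabilities) -> Grade:
    """Highest-probability grade; exact ties resolve toward the narrower grade."""
    probs = p.as_array()
    # np.argmax returns the first maximum, i.e. the narrower grade on ties
    return Grade(int(np.argmax(probs)))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _coerce_X(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if isinstance(X, Mapping):
        names = list(X)
        return np.column_stack([np.asarray(X[k], float) for k in names]), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _nll_grad_natural(theta: np.ndarray, X: np.ndarray, y: np.ndarray, k: int):
    """Negative log-likelihood and gradient in (a_1..a_{k-1}, beta) coords."""
    a = theta[:k - 1]
    b = theta[k - 1:]
    eta = X @ b if X.shape[1] else np.zeros(len(y))
    G = expit(a[None, :] - eta[:, None])                   # (n, k-1)
    Gf = np.concatenate([np.zeros((len(y), 1)), G, np.ones((len(y), 1))], axis=1)
    sp = np.concatenate([np.zeros((len(y), 1)), G * (1 - G),
                         np.zeros((len(y), 1))], axis=1)
    idx = np.arange(len(y))
    p = Gf[idx, y + 1] - Gf[idx, y]
    p = np.clip(p, 1e-300, None)
    nll = -float(np.log(p).sum())

    ga = np.zeros(k - 1)
    for m in range(1, k):
        contrib = sp[idx, m] * ((y + 1 == m).astype(float) - (y == m).astype(float))
        ga[m - 1] = -float((contrib / p).sum())
    wcoef = (sp[idx, y + 1] - sp[idx, y]) / p
    gb = X.T @ wcoef if X.shape[1] else np.zeros(0)
    return nll, np.concatenate([ga, gb])


def _natural_from_repar(t: np.ndarray, k: int) -> np.ndarray:
    """(a1, log-gaps, beta) -> (a1..a_{k-1}, beta)."""
    a = np.empty(k - 1)
    a[0] = t[0]
    for m in range(1, k - 1):
        a[m] = a[m - 1] + math.exp(t[m])
    return np.concatenate([a, t[k - 1:]])


def _fit_cumulative_logit(X: np.ndarray, y: np.ndarray, k: int,
                          gtol: float = 1e-8):
    n, p = X.shape
    counts = np.bincount(y, minlength=k)
    if np.any(counts == 0):
        raise DegenerateLabelsError(
            f"degenerate labels: class counts {counts.tolist()}")

    cum = np.cumsum(counts)[: k - 1] / n
    a_emp = np.log(cum / (1 - cum))
    gaps = np.maximum(np.diff(a_emp), 1e-3)
    start0 = np.concatenate([[a_emp[0]], np.log(gaps), np.zeros(p)])

    def obj(t):
        theta = _natural_from_repar(t, k)
        nll, g = _nll_grad_natural(theta, X, y, k)
        # chain rule to (a1, log-gap..., beta)
        gt = np.empty_like(t)
        gt[0] = g[: k - 1].sum()
        for m in range(1, k - 1):
            gt[m] = math.exp(t[m]) * g[m: k - 1].sum()
        gt[k - 1:] = g[k - 1:]
        return nll, gt

    best = None
    rng = np.random.default_rng(12345)
    starts = [start0]
    for _ in range(2):
        starts.append(start0 + rng.normal(0.0, 0.5, size=start0.shape))
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(obj, s, jac=True, method="BFGS",
                                    options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res

    theta = _natural_from_repar(best.x, k)
    nll, grad = _nll_grad_natural(theta, X, y, k)
    if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e3 \
            or nll / n < 1e-8:
        raise NonFiniteMLEError(
            "non-finite MLE: likelihood unbounded (complete separation); "
            f"parameter magnitudes reached {np.max(np.abs(theta)):.3g}")
    if np.linalg.norm(grad) > max(1e-5, 1e-6 * n):
        warnings.warn("ordered-logit optimizer did not reach the requested "
                      f"gradient tolerance (|g| = {np.linalg.norm(grad):.2e})",
                      RuntimeWarning, stacklevel=2)

    # observed information: central finite differences of the analytic gradient
    dim = len(theta)
    H = np.empty((dim, dim))
    for j in range(dim):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _nll_grad_natural(tp, X, y, k)
        _, gm = _nll_grad_natural(tm, X, y, k)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return theta, -nll, cov, se


@dataclass
class OrderedLogitFit:
    """Maximum-likelihood fit of the three-grade proportional-odds model."""

    params: OrderedLogitParams
    loglik: float
    se: dict[str, float]
    cov: np.ndarray = field(repr=False)
    n: int = 0

    @property
    def param_names(self) -> list[str]:
        return ["alpha1", "alpha2", *self.params.beta]


@dataclass
class BinaryLogitFit:
    """Logistic open/closed fit: P(closed) = expit(alpha - beta*x)."""

    alpha: float
    beta: dict[str, float]
    loglik: float
    se: dict[str, float]
    cov: np.ndarray = field(repr=False)
    n: int = 0

    def predict_closed(self, x: Mapping[str, float]) -> float:
        eta = sum(self.beta[k] * float(x[k]) for k in self.beta)
        return float(expit(self.alpha - eta))


def fit_ordered_logit(X, y: Sequence[Grade | int]) -> OrderedLogitFit:
    """Fit the three-grade proportional-odds model by maximum likelihood.

    ``X`` is a DataFrame / mapping of named predictor columns (or a plain
    array); ``y`` holds :class:`Grade` labels.  Raises
    :class:`DegenerateLabelsError` when a grade is unobserved and
    :class:`NonFiniteMLEError` under complete separation.
    """
    Xa, names = _coerce_X(X)
    ya = np.asarray([int(v) for v in y])
    if Xa.shape[0] != len(ya):
        raise ValueError("X and y lengths differ")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("predictors must be finite")
    theta, ll, cov, se = _fit_cumulative_logit(Xa, ya, k=3)
    params = OrderedLogitParams(alpha1=float(theta[0]), alpha2=float(theta[1]),
                                beta=dict(zip(names, theta[2:])))
    se_d = dict(zip(["alpha1", "alpha2", *names], se))
    return OrderedLogitFit(params=params, loglik=ll, se=se_d, cov=cov,
                           n=len(ya))


def fit_binary_logit(X, y_open: Sequence[bool]) -> BinaryLogitFit:
    """Fit the open/closed logistic model (True = open).

    Internally the model is the two-category cumulative logit with
    P(closed) = expit(alpha - beta*x), matching the sign convention of the
    three-grade model.
    """
    Xa, names = _coerce_X(X)
    # category codes: closed = 0 (narrower), open = 1
    yb = np.asarray([1 if (o is True or o == 1) else 0 for o in y_open])
    theta, ll, cov, se = _fit_cumulative_logit(Xa, yb, k=2)
    return BinaryLogitFit(alpha=float(theta[0]),
                          beta=dict(zip(names, theta[1:])),
                          loglik=ll,
                          se=dict(zip(["alpha", *names], se)),
                          cov=cov, n=len(yb))


@dataclass
class StepwiseResult:
    """Outcome of stepwise predictor selection."""

    selected: list[str]
    p_values: dict[str, float]
    fit: OrderedLogitFit | None
    null_loglik: float


def _loglik_only(Xa: np.ndarray, ya: np.ndarray, k: int = 3) -> float:
    _, ll, _, _ = _fit_cumulative_logit(Xa, ya, k)
    return ll


def stepwise_select(X: pd.DataFrame, y: Sequence[Grade | int],
                    entry: float = 0.05, removal: float = 0.10
                    ) -> StepwiseResult:
    """Forward stepwise selection on the ordered-logit likelihood.

    At each step the candidate with the smallest likelihood-ratio-test P is
    added if P < ``entry`` (ties broken by column order), then retained terms
    are backward-checked and dropped at P > ``removal``.  Returns the selected
    names, the last LRT P value seen for every candidate, and the final fit
    (None when nothing is selected).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    ya = np.asarray([int(v) for v in y])
    cols = list(X.columns)
    selected: list[str] = []
    pvals: dict[str, float] = {}

    def ll_of(names: list[str]) -> float:
        Xa = X[names].to_numpy(float) if names else np.empty((len(ya), 0))
        return _loglik_only(Xa, ya)

    ll_null = ll_of([])
    ll_cur = ll_null
    for _ in range(2 * len(cols) + 2):
        changed = False
        # forward step
        best_name, best_p = None, None
        for c in cols:
            if c in selected:
                continue
            ll_c = ll_of(selected + [c])
            lr = max(0.0, 2.0 * (ll_c - ll_cur))
            p = float(chi2.sf(lr, df=1))
            pvals[c] = p
            if p < entry and (best_p is None or p < best_p - 1e-15):
                best_name, best_p = c, p
        if best_name is not None:
            selected.append(best_name)
            ll_cur = ll_of(selected)
            changed = True
        # backward step
        if selected:
            worst_name, worst_p = None, None
            for c in selected:
                rest = [s for s in selected if s != c]
                ll_r = ll_of(rest)
                lr = max(0.0, 2.0 * (ll_cur - ll_r))
                p = float(chi2.sf(lr, df=1))
                pvals[c] = p
                if worst_p is None or p > worst_p:
                    worst_name, worst_p = c, p
            if worst_p is not None and worst_p > removal:
                selected.remove(worst_name)
                ll_cur = ll_of(selected)
                changed = True
        if not changed:
            break

    fit = fit_ordered_logit(X[selected], ya) if selected else None
    return StepwiseResult(selected=selected, p_values=pvals, fit=fit,
                          null_loglik=ll_null)
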