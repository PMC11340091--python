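"""Survival estimation and modelling.

Kaplan-Meier curves, log-rank tests and reverse-KM follow-up are thin
wrappers around lifelines. Cox models use the Breslow approximation for
tied event times throughout: the unpenalized fit is a Newton-Raphson
maximizer of the Breslow partial likelihood with exact observed
information (Wald CIs), and the elastic-net penalized fit is a
glmnet-style IRLS + coordinate-descent path solver (see ``_solver``).

Conventions for the penalized fit: predictor columns are centered and
scaled to unit (population) variance inside the solver; coefficients are
reported back on the input scale. The penalty at level ``lam`` with
mixing ``alpha`` is ``lam * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)``
added to the negative log partial likelihood divided by n, so ``lam``
matches the lambda of the canonical elastic-net Cox software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from ._solver import fit_single_lambda

__all__ = [
    "SurvivalOutcome",
    "KMCurve",
    "CoxFit",
    "PenalizedCoxFit",
    "LambdaSelection",
    "ConvergenceError",
    "km_estimate",
    "logrank_test",
    "reverse_km_median_followup",
    "fit_cox",
    "fit_penalized_cox",
    "penalized_cox_path",
    "compute_lambda_max",
    "select_lambda_cv",
    "prognostic_index",
    "breslow_loglik",
]


class ConvergenceError(RuntimeError):
    """Raised when a Cox fit fails to converge (including separation)."""


@dataclass
class SurvivalOutcome:
    """Disease-free survival outcome: months of follow-up and event flag."""

    time: np.ndarray
    event: np.ndarray
    patient_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.patient_id is None:
            self.patient_id = np.array([f"P{i:04d}" for i in range(len(self.time))])
        else:
            self.patient_id = np.asarray(self.patient_id)
            if len(np.unique(self.patient_id)) != len(self.patient_id):
                raise ValueError("duplicate patient ids")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx], self.patient_id[idx])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, time_col: str = "dfs_months",
                   event_col: str = "dfs_event",
                   id_col: str = "patient_id") -> "SurvivalOutcome":
        ids = df[id_col].to_numpy() if id_col in df else None
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy(), ids)


class _SortedSurv:
    """Follow-up times sorted ascending with tie-group bookkeeping."""

    def __init__(self, outcome: SurvivalOutcome):
        order = np.argsort(outcome.time, kind="mergesort")
        self.order = order
        self.time = outcome.time[order]
        self.delta = outcome.event[order].astype(np.int8)
        self.first_idx = np.searchsorted(self.time, self.time, side="left").astype(np.int64)
        self.last_idx = (np.searchsorted(self.time, self.time, side="right") - 1).astype(np.int64)

    def loglik(self, eta_sorted: np.ndarray) -> float:
        exp_eta = np.exp(eta_sorted)
        suffix = np.cumsum(exp_eta[::-1])[::-1]
        s0 = suffix[self.first_idx]
        ev = self.delta == 1
        return float(np.sum(eta_sorted[ev]) - np.sum(np.log(s0[ev])))


def breslow_loglik(eta: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    srt = _SortedSurv(outcome)
    return srt.loglik(np.asarray(eta, dtype=float)[srt.order])


# ---------------------------------------------------------------------------
# Nonparametric estimation


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # nan when not reached
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def _km_one(time, event) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    med = kmf.median_survival_time_
    return KMCurve(
        times=tab.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=tab["at_risk"].to_numpy(),
        median=float(med) if np.isfinite(med) else float("nan"),
        n=len(time),
        n_events=int(np.sum(event)),
    )


def km_estimate(outcome: SurvivalOutcome,
                groups: Sequence | None = None) -> dict[object, KMCurve]:
    """Product-limit estimator, overall or per group label."""
    if groups is None:
        return {"all": _km_one(outcome.time, outcome.event)}
    groups = np.asarray(groups)
    out: dict[object, KMCurve] = {}
    for g in pd.unique(groups):
        m = groups == g
        if not m.any():
            raise ValueError(f"empty group {g!r}")
        out[g] = _km_one(outcome.time[m], outcome.event[m])
    return out


def logrank_test(outcome: SurvivalOutcome, groups: Sequence) -> tuple[float, int, float]:
    """Log-rank chi-square statistic, degrees of freedom and p-value."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(outcome.time, groups, outcome.event)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def reverse_km_median_followup(outcome: SurvivalOutcome) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censorings are treated as events and events as censorings; the median
    of that curve estimates the median potential follow-up. Returns nan
    when not reached (e.g. everyone had an event).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(outcome.time, 1 - outcome.event)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")


# ---------------------------------------------------------------------------
# Standard Cox (Breslow)


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    loglik: float
    n: int
    n_events: int

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta).rename("HR")

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return pd.DataFrame({"hr_lower95": lo, "hr_upper95": hi})

    @property
    def p_values(self) -> pd.Series:
        from scipy.stats import chi2

        z2 = (self.beta / self.se) ** 2
        return pd.Series(chi2.sf(z2, df=1), index=self.beta.index, name="p")

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame({
            "coef": self.beta, "hr": self.hr,
            "hr_lower95": ci["hr_lower95"], "hr_upper95": ci["hr_upper95"],
            "p": self.p_values,
        })


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_cox(X, outcome: SurvivalOutcome, max_iter: int = 60,
            tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximizer of the Breslow partial likelihood.

    Reports Wald 95% CIs from the inverse observed information. Raises
    :class:`ConvergenceError` on non-convergence or (quasi-)separation
    rather than silently clamping coefficients.
    """
    arr, names = _as_design(X)
    n, p = arr.shape
    if np.any(np.std(arr, axis=0) == 0):
        raise ValueError("constant columns in the design matrix")
    if outcome.event.sum() < 1:
        raise ValueError("no events")
    srt = _SortedSurv(outcome)
    Xs = arr[srt.order]
    delta = srt.delta.astype(bool)
    beta = np.zeros(p)
    ll = srt.loglik(Xs @ beta)
    for _ in range(max_iter):
        eta = Xs @ beta
        exp_eta = np.exp(eta)
        s0 = np.cumsum(exp_eta[::-1])[::-1][srt.first_idx]
        s1 = np.cumsum((exp_eta[:, None] * Xs)[::-1], axis=0)[::-1][srt.first_idx]
        xxw = exp_eta[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
        s2 = np.cumsum(xxw[::-1], axis=0)[::-1][srt.first_idx]
        xbar = s1 / s0[:, None]
        grad = np.sum(Xs[delta] - xbar[delta], axis=0)
        info = np.sum(s2[delta] / s0[delta, None, None]
                      - xbar[delta][:, :, None] * xbar[delta][:, None, :], axis=0)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConvergenceError("singular information matrix") from exc
        # step halving to guarantee ascent
        new_ll = -np.inf
        for _h in range(30):
            cand = beta + step
            new_ll = srt.loglik(Xs @ cand)
            if new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(beta)) > 20:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 20): likely separation")
        converged = np.max(np.abs(grad)) < tol or np.max(np.abs(step)) < 1e-12
        ll = new_ll
        if converged:
            break
    else:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(pd.Series(beta, index=names, name="coef"),
                  pd.Series(se, index=names, name="se"),
                  loglik=ll, n=n, n_events=int(outcome.event.sum()))


# ---------------------------------------------------------------------------
# Elastic-net penalized Cox


@dataclass
class PenalizedCoxFit:
    beta: pd.Series           # input scale
    alpha: float              # elastic-net mixing (l1 weight)
    lam: float
    center: np.ndarray
    scale: np.ndarray
    lambda_path: np.ndarray | None = None
    beta_path: np.ndarray | None = None  # input scale, (n_lambda, p)
    cv_deviance: np.ndarray | None = None
    n_iter: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.beta.to_numpy() != 0))

    def linear_predictor(self, X) -> np.ndarray:
        arr, _ = _as_design(X)
        return (arr - self.center) @ self.beta.to_numpy()


def _standardize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = arr.mean(axis=0)
    scale = arr.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (arr - center) / scale, center, scale


def compute_lambda_max(X, outcome: SurvivalOutcome, alpha: float = 0.9,
                       penalty_factor: np.ndarray | None = None) -> float:
    """Smallest lambda at which all penalized coefficients are zero."""
    arr, _ = _as_design(X)
    n, p = arr.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    Xstd, _, _ = _standardize(arr)
    srt = _SortedSurv(outcome)
    Xs = Xstd[srt.order]
    # score of the null model: delta - cumulative hazard at eta = 0
    s0 = np.cumsum(np.ones(n)[::-1])[::-1][srt.first_idx]
    contrib = np.where(srt.delta == 1, 1.0 / s0, 0.0)
    mu0 = np.cumsum(contrib)[srt.last_idx]
    g = Xs.T @ (srt.delta - mu0) / n
    pen = pf > 0
    if not pen.any():
        return 0.0
    # tiny inflation so that a fit at exactly this value is exactly zero
    # despite floating-point rounding of the score
    return float(np.max(np.abs(g[pen]) / (alpha * pf[pen]))) * (1 + 1e-10)


def _make_lambda_path(lambda_max: float, n_lambdas: int,
                      lambda_min_ratio: float) -> np.ndarray:
    return lambda_max * np.exp(
        np.linspace(0.0, np.log(lambda_min_ratio), n_lambdas))


def penalized_cox_path(X, outcome: SurvivalOutcome, alpha: float = 0.9,
                       lambdas: np.ndarray | None = None,
                       n_lambdas: int = 30, lambda_min_ratio: float = 0.1,
                       penalty_factor: np.ndarray | None = None,
                       tol: float = 1e-7, max_irls: int = 300,
                       max_passes: int = 20000,
                       strict: bool = True) -> PenalizedCoxFit:
    """Fit the elastic-net Cox solution path over a descending lambda grid.

    Returns a :class:`PenalizedCoxFit` whose ``beta``/``lam`` refer to the
    last (smallest) lambda and whose ``beta_path`` holds the whole path on
    the input scale.

    With ``strict=False``, exhausting the iteration budget keeps the last
    iterate instead of raising: the line-searched IRLS is monotone, so
    that iterate is a valid descent point. This matters for quasi-separated
    unpenalized covariates, whose likelihood is flat at the boundary and
    admits no finite optimum to converge to.
    """
    if not 0 < alpha <= 1:
        raise ValueError("mixing parameter alpha must be in (0, 1]")
    arr, names = _as_design(X)
    n, p = arr.shape
    if len(outcome) != n:
        raise ValueError("design matrix and outcome are misaligned")
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    Xstd, center, scale = _standardize(arr)
    srt = _SortedSurv(outcome)
    Xs = np.ascontiguousarray(Xstd[srt.order])
    delta = srt.delta
    if lambdas is None:
        lmax = compute_lambda_max(arr, outcome, alpha, pf)
        lambdas = _make_lambda_path(lmax, n_lambdas, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    beta = np.zeros(p)
    eta = np.zeros(n)
    path = np.empty((len(lambdas), p))
    total_iter = 0
    for k, lam in enumerate(lambdas):
        it = fit_single_lambda(Xs, delta, srt.first_idx, srt.last_idx,
                               beta, eta, lam, alpha, pf,
                               tol, max_irls, max_passes)
        if it < 0 and strict:
            raise ConvergenceError(
                f"penalized Cox did not converge at lambda={lam:.4g}")
        total_iter += abs(it)
        path[k] = beta / scale
    fit = PenalizedCoxFit(
        beta=pd.Series(path[-1], index=names, name="coef"),
        alpha=alpha, lam=float(lambdas[-1]), center=center, scale=scale,
        lambda_path=lambdas, beta_path=path, n_iter=total_iter,
        provenance={"ties": "breslow", "standardized": True},
    )
    return fit


def fit_penalized_cox(X, outcome: SurvivalOutcome, lam: float,
                      alpha: float = 0.9,
                      penalty_factor: np.ndarray | None = None,
                      tol: float = 1e-7, strict: bool = True) -> PenalizedCoxFit:
    """Elastic-net Cox fit at a single lambda (warm-started short path).

    At ``lam >= lambda_max`` every penalized coefficient is exactly zero.
    """
    arr, _ = _as_design(X)
    p = arr.shape[1]
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    lmax = compute_lambda_max(arr, outcome, alpha, pf)
    if lam >= lmax and np.all(pf > 0):
        lambdas = np.array([lam])
    elif lam >= lmax:
        lambdas = np.array([lam])
    else:
        # short geometric descent into lam for warm-start stability
        n_steps = max(2, int(np.ceil(np.log(max(lmax, 1e-12) / max(lam, 1e-12)) / np.log(2.5))) + 1)
        lambdas = np.geomspace(lmax, lam, n_steps) if lam > 0 else np.append(
            np.geomspace(lmax, max(lmax * 1e-4, 1e-10), max(n_steps - 1, 2)), 0.0)
    fit = penalized_cox_path(X, outcome, alpha=alpha, lambdas=lambdas,
                             penalty_factor=pf, tol=tol, strict=strict)
    fit.lam = float(lam)
    return fit


@dataclass
class LambdaSelection:
    lambda_opt: float
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    k: int
    provenance: dict = field(default_factory=dict)


def select_lambda_cv(X, outcome: SurvivalOutcome, k: int = 5,
                     alpha: float = 0.9, seed: int = 0,
                     n_lambdas: int = 30, lambda_min_ratio: float = 0.1,
                     penalty_factor: np.ndarray | None = None,
                     tol: float = 1e-7, stratify_events: bool = True,
                     patience: int | None = 5) -> LambdaSelection:
    """Pick lambda minimizing the k-fold cross-validated partial-likelihood
    deviance (Verweij-van Houwelingen formulation) over a log-spaced path.

    All folds are advanced down the path together with warm starts; with
    ``patience`` set (default 5), the descent stops once the running CV
    minimum has not improved for that many consecutive lambdas, which
    skips the expensive dense tail of the path when the deviance curve
    has already turned upward (the curve is near-convex in practice).
    """
    from .crossval import make_folds

    arr, _ = _as_design(X)
    n, p = arr.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    lmax = compute_lambda_max(arr, outcome, alpha, pf)
    if lmax == 0:
        return LambdaSelection(0.0, np.zeros(1), np.zeros(1), k)
    lambdas = _make_lambda_path(lmax, n_lambdas, lambda_min_ratio)
    folds = make_folds(outcome, k=k, seed=seed, stratify_events=stratify_events)
    srt_all = _SortedSurv(outcome)
    # per-fold warm-start state
    states = []
    for fold in range(k):
        train = folds != fold
        out_tr = outcome.subset(train)
        Xtr = arr[train]
        Xstd, center, scale = _standardize(Xtr)
        srt_tr = _SortedSurv(out_tr)
        states.append({
            "train": train,
            "Xs": np.ascontiguousarray(Xstd[srt_tr.order]),
            "srt_tr": srt_tr,
            "Z_all": (arr - center) / scale,  # standardized on the fold's scale
            "beta": np.zeros(p),
            "eta": np.zeros(train.sum()),
        })
    dev = np.full(len(lambdas), np.nan)
    best, best_j = np.inf, 0
    n_used = 0
    for j, lam in enumerate(lambdas):
        d = 0.0
        for st in states:
            # non-convergence (it < 0) keeps the last monotone iterate,
            # which happens only for flat quasi-separated directions and
            # is the right point to evaluate the CV deviance at
            fit_single_lambda(st["Xs"], st["srt_tr"].delta,
                              st["srt_tr"].first_idx, st["srt_tr"].last_idx,
                              st["beta"], st["eta"], lam, alpha, pf,
                              tol, 300, 20000)
            eta_all = st["Z_all"] @ st["beta"]
            ll_all = srt_all.loglik(eta_all[srt_all.order])
            ll_tr = st["srt_tr"].loglik(
                eta_all[st["train"]][st["srt_tr"].order])
            d += -2.0 * (ll_all - ll_tr)
        dev[j] = d
        n_used = j + 1
        if d < best:
            best, best_j = d, j
        if patience is not None and j - best_j >= patience:
            break
    return LambdaSelection(
        float(lambdas[best_j]), lambdas[:n_used], dev[:n_used], k,
        provenance={"cv_deviance": "verweij-van-houwelingen",
                    "rule": "min", "seed": seed, "patience": patience},
    )


def prognostic_index(fit: PenalizedCoxFit | CoxFit, X) -> np.ndarray:
    """Per-patient linear predictor x'beta; higher = higher hazard."""
    if isinstance(fit, PenalizedCoxFit):
        return fit.linear_predictor(X)
    arr, _ = _as_design(X)
    return arr @ fit.beta.to_numpy()
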