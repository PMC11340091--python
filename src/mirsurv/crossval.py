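"""Cross-validated predictive-accuracy machinery.

Out-of-fold prognostic indices (pre-validation in the sense of Simon et
al.), median-split cross-validated Kaplan-Meier curves with their log-rank
statistic, and IPCW time-dependent ROC/AUC at a landmark timepoint.

Every patient is scored exactly once, by a model whose training data never
contained that patient; penalized models re-select lambda by an inner
5-fold CV restricted to the training portion of each outer fold, so no
information leaks from the held-out patients into their own scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import KFold, StratifiedKFold

from .survival import (
    ConvergenceError,
    KMCurve,
    SurvivalOutcome,
    fit_cox,
    fit_penalized_cox,
    km_estimate,
    logrank_test,
    select_lambda_cv,
)

__all__ = [
    "ModelSpec",
    "CVPrognosticIndex",
    "ROCResult",
    "make_folds",
    "cv_prognostic_indices",
    "cv_km_logrank",
    "cv_landmark_roc",
    "cv_statistics",
    "standard_model_specs",
]


@dataclass(frozen=True)
class ModelSpec:
    """One of the three model specifications of the analysis plan.

    ``blocks`` are predictor-block names looked up in the block mapping
    passed to :func:`cv_prognostic_indices`; blocks named ``clinical`` are
    exempted from the elastic-net penalty by default (the standard
    prognostic factors are forced into the combined model).
    """

    name: str
    blocks: tuple[str, ...]
    fitter: str  # "penalized" | "standard"
    penalize_clinical: bool = False

    def __post_init__(self):
        if self.fitter not in ("penalized", "standard"):
            raise ValueError(f"unknown fitter {self.fitter!r}")


def standard_model_specs(mirna_blocks: tuple[str, ...] = ("mirna",)) -> dict[str, ModelSpec]:
    """The three canonical specifications: miRNA-only (elastic net),
    miRNA + clinical (elastic net, clinical unpenalized), clinical-only
    (standard Cox)."""
    return {
        "model1": ModelSpec("model1_mirna_only", tuple(mirna_blocks), "penalized"),
        "model2": ModelSpec("model2_combined", tuple(mirna_blocks) + ("clinical",), "penalized"),
        "model3": ModelSpec("model3_clinical_only", ("clinical",), "standard"),
    }


@dataclass
class CVPrognosticIndex:
    scores: np.ndarray          # pooled out-of-fold linear predictors
    fold_ids: np.ndarray
    risk_group: np.ndarray      # "low" / "high"
    median: float
    fold_coefs: list[pd.Series]
    fold_lambdas: list[float]
    spec_name: str


@dataclass
class ROCResult:
    landmark: float
    fp: np.ndarray
    tp: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def make_folds(outcome: SurvivalOutcome, k: int = 5, seed: int = 0,
               stratify_events: bool = True) -> np.ndarray:
    """Deterministic near-equal-size fold assignment, stratified on the
    event indicator by default so every training portion keeps events."""
    n = len(outcome)
    if k < 2 or k > n:
        raise ValueError("k must be between 2 and n")
    fold_ids = np.empty(n, dtype=int)
    if stratify_events and 0 < outcome.event.sum() < n:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), outcome.event)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    for f, (_, test_idx) in enumerate(splits):
        fold_ids[test_idx] = f
    return fold_ids


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(fold)]).generate_state(1)[0] % (2**31))


def _assemble(blocks: Mapping[str, pd.DataFrame], spec: ModelSpec):
    mats, pf, names = [], [], []
    for b in spec.blocks:
        df = blocks[b]
        mats.append(df.to_numpy(dtype=float))
        w = 0.0 if (b == "clinical" and not spec.penalize_clinical
                    and spec.fitter == "penalized") else 1.0
        pf.extend([w] * df.shape[1])
        names.extend(df.columns)
    X = np.hstack(mats)
    return X, np.asarray(pf), names


def cv_prognostic_indices(blocks: Mapping[str, pd.DataFrame],
                          outcome: SurvivalOutcome, spec: ModelSpec,
                          folds: np.ndarray, alpha: float = 0.9,
                          seed: int = 0, inner_k: int = 5,
                          n_lambdas: int = 30,
                          lambda_min_ratio: float = 0.1,
                          block_builder=None,
                          median_split: str = "pooled") -> CVPrognosticIndex:
    """Out-of-fold prognostic indices and median-split risk groups.

    For each fold the model is fitted on the remaining folds (penalized
    models choose lambda by ``inner_k``-fold CV on that training portion
    only, with a seed derived from the fold index, never from the data)
    and the held-out patients are scored. Risk groups split at the median
    of the pooled out-of-fold scores; at-median scores go to the low-risk
    group.

    ``block_builder``, when given, is called per fold with the training
    mask and must return ``(blocks_train, blocks_test)``; it supports the
    within-training-fold normalization mode, where the miRNA expression
    block itself is recomputed on the training samples alone.
    """
    if block_builder is None:
        X, pf, names = _assemble(blocks, spec)
        n = X.shape[0]
        if len(outcome) != n:
            raise ValueError("blocks and outcome are misaligned")
    else:
        n = len(outcome)
    scores = np.full(n, np.nan)
    fold_coefs: list[pd.Series] = []
    fold_lambdas: list[float] = []
    for f in np.unique(folds):
        train = folds != f
        test = ~train
        out_tr = outcome.subset(train)
        if out_tr.event.sum() == 0:
            raise ValueError(f"training portion of fold {f} has zero events")
        if block_builder is None:
            X_tr, X_te, pf_f, names_f = X[train], X[test], pf, names
        else:
            blocks_tr, blocks_te = block_builder(train)
            X_tr, pf_f, names_f = _assemble(blocks_tr, spec)
            X_te, _, _ = _assemble(blocks_te, spec)
        if spec.fitter == "standard":
            try:
                fit = fit_cox(pd.DataFrame(X_tr, columns=names_f), out_tr)
                beta = fit.beta
            except ConvergenceError:
                # quasi-separation in a small training fold: stabilize with
                # a mild, mostly-ridge penalty so the fold still scores
                pfit = fit_penalized_cox(X_tr, out_tr, lam=1e-2, alpha=0.05,
                                         strict=False)
                beta = pd.Series(pfit.beta.to_numpy(), index=names_f)
            scores[test] = X_te @ beta.to_numpy()
            fold_coefs.append(beta)
            fold_lambdas.append(float("nan"))
        else:
            sel = select_lambda_cv(X_tr, out_tr, k=inner_k, alpha=alpha,
                                   seed=_fold_seed(seed, int(f)),
                                   n_lambdas=n_lambdas,
                                   lambda_min_ratio=lambda_min_ratio,
                                   penalty_factor=pf_f)
            fit = fit_penalized_cox(X_tr, out_tr, lam=sel.lambda_opt,
                                    alpha=alpha, penalty_factor=pf_f,
                                    strict=False)
            scores[test] = (X_te - fit.center) @ fit.beta.to_numpy()
            fold_coefs.append(pd.Series(fit.beta.to_numpy(), index=names_f))
            fold_lambdas.append(sel.lambda_opt)
    if median_split == "pooled":
        med = float(np.median(scores))
        group = np.where(scores > med, "high", "low")
    elif median_split == "per_fold":
        med = float("nan")
        group = np.empty(n, dtype=object)
        for f in np.unique(folds):
            m = folds == f
            group[m] = np.where(scores[m] > np.median(scores[m]), "high", "low")
        group = group.astype(str)
    else:
        raise ValueError("median_split must be 'pooled' or 'per_fold'")
    return CVPrognosticIndex(scores, np.asarray(folds), group, med,
                             fold_coefs, fold_lambdas, spec.name)


def cv_km_logrank(cvpi: CVPrognosticIndex,
                  outcome: SurvivalOutcome) -> tuple[dict[str, KMCurve], float]:
    """KM curves of the low/high out-of-fold risk groups and the log-rank
    chi-square statistic between them.

    The statistic is returned raw (its null distribution under
    cross-validation must come from permutations, not chi-square). A
    degenerate split (all scores tied, e.g. when every inner model is
    empty) yields statistic 0 by convention: no separation was achieved.
    """
    labels = np.unique(cvpi.risk_group)
    if len(labels) < 2:
        return km_estimate(outcome, cvpi.risk_group), 0.0
    curves = km_estimate(outcome, cvpi.risk_group)
    stat, _, _ = logrank_test(outcome, cvpi.risk_group)
    return curves, float(stat)


def _censoring_survival(outcome: SurvivalOutcome):
    kmf = KaplanMeierFitter()
    kmf.fit(outcome.time, 1 - outcome.event)
    sf = kmf.survival_function_["KM_estimate"]
    return sf.index.to_numpy(dtype=float), sf.to_numpy(dtype=float)


def _g_at(t, times, probs, before: bool) -> float:
    side = "left" if before else "right"
    i = np.searchsorted(times, t, side=side) - 1
    return float(probs[i]) if i >= 0 else 1.0


def cv_landmark_roc(scores: np.ndarray | CVPrognosticIndex,
                    outcome: SurvivalOutcome,
                    landmark: float = 24.0) -> ROCResult:
    """IPCW cumulative-case / dynamic-control ROC at the landmark time.

    Cases are patients with an event by the landmark, controls are
    event-free beyond it; patients censored before the landmark drop out
    and the remaining cases are reweighted by the inverse of the
    censoring survival function (reverse-KM) at their event time. The AUC
    is the trapezoidal integral of the curve; tied scores contribute
    diagonal segments (so a constant score gives exactly 0.5).
    """
    if isinstance(scores, CVPrognosticIndex):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    t, e = outcome.time, outcome.event
    case = (e == 1) & (t <= landmark)
    control = t > landmark
    n_cases, n_controls = int(case.sum()), int(control.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("no cases or no controls evaluable at the landmark")
    gt, gp = _censoring_survival(outcome)
    w = np.zeros(len(t))
    for i in np.flatnonzero(case):
        g = _g_at(t[i], gt, gp, before=True)
        w[i] = 1.0 / max(g, 1e-12)
    w_ctrl = np.where(control, 1.0, 0.0)
    keep = case | control
    s = scores[keep]
    wc = w[keep]
    wq = w_ctrl[keep]
    order = np.argsort(-s, kind="mergesort")
    s, wc, wq = s[order], wc[order], wq[order]
    # group tied scores: one ROC vertex per distinct score value
    boundaries = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundaries, len(s) - 1)
    cum_case = np.cumsum(wc)[ends]
    cum_ctrl = np.cumsum(wq)[ends]
    tp = np.concatenate([[0.0], cum_case / cum_case[-1]])
    fp = np.concatenate([[0.0], cum_ctrl / cum_ctrl[-1]])
    auc = float(np.trapezoid(tp, fp))
    return ROCResult(landmark, fp, tp, auc, n_cases, n_controls)


def cv_statistics(blocks: Mapping[str, pd.DataFrame], outcome: SurvivalOutcome,
                  spec: ModelSpec, k: int = 5, seed: int = 0,
                  landmark: float = 24.0, alpha: float = 0.9,
                  folds: np.ndarray | None = None,
                  stratify_events: bool = True,
                  n_lambdas: int = 30,
                  lambda_min_ratio: float = 0.1,
                  block_builder=None) -> dict:
    """Run the full CV evaluation of one model specification.

    Returns the pooled out-of-fold index, the CV-KM log-rank statistic and
    the CV landmark AUC in one pass (the permutation tests reuse this)."""
    if folds is None:
        folds = make_folds(outcome, k=k, seed=seed, stratify_events=stratify_events)
    cvpi = cv_prognostic_indices(blocks, outcome, spec, folds, alpha=alpha,
                                 seed=seed, n_lambdas=n_lambdas,
                                 lambda_min_ratio=lambda_min_ratio,
                                 block_builder=block_builder)
    curves, logrank_stat = cv_km_logrank(cvpi, outcome)
    roc = cv_landmark_roc(cvpi, outcome, landmark=landmark)
    return {"cvpi": cvpi, "curves": curves, "logrank": logrank_stat,
            "auc": roc.auc, "roc": roc, "folds": folds}
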