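"""Orchestration of the full three-model prognostic analysis.

From one or two raw miRNA count matrices (e.g. a cell-free and an
extracellular-vesicle fraction measured on overlapping patients) plus a
clinical/outcome table, runs: unsupervised filtering -> TMM + Blom
normalization -> Models 1-3 (miRNA-only elastic net, combined elastic
net, clinical-only Cox) -> 5-fold cross-validated KM / landmark-ROC
evaluation -> permutation tests of absolute and incremental accuracy.
When two matrices are given the plan is run per matrix and then on the
patient intersection with both blocks concatenated (ids prefixed by the
matrix label).

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossval import cv_statistics, make_folds, standard_model_specs
from .permutation import added_value_test, permute_full_null
from .preprocess import (CountMatrix, ExpressionMatrix, filter_mirnas,
                         filter_samples, fold_normalization, preprocess_counts)
from .survival import (SurvivalOutcome, fit_cox, fit_penalized_cox,
                       reverse_km_median_followup, select_lambda_cv)

logger = logging.getLogger("mirsurv")

__all__ = ["AnalysisConfig", "run_full_analysis", "clinical_design",
           "cohort_analysis_inputs", "load_cohort_files", "write_report"]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``counts`` maps a matrix label (e.g. ``cf``/``ev``, or ``mirna`` for a
    single matrix) to a counts TSV path. The clinical CSV must contain
    ``patient_id, age, sex, stage`` and, unless a separate outcome CSV is
    given, ``dfs_months, dfs_event``.
    """

    counts: dict = field(default_factory=dict)
    clinical: str = ""
    outcome: str | None = None
    q3_threshold: float = 5.0
    alpha: float = 0.9
    k_folds: int = 5
    landmark: float = 24.0
    n_permutations: int = 500
    seed: int = 0
    within_fold_normalization: bool = False
    fixed_permutation_folds: bool = False
    welch: bool = False
    n_lambdas: int = 30

    def __post_init__(self) -> None:
        if self.landmark <= 0:
            raise ValueError("landmark must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Design matrix of the standard prognostic factors.

    Sex enters as male-vs-female indicator, age as a continuous 1-unit
    (year) increment, pathological stage as two dummies (II vs I,
    IIIA vs I)."""
    df = clinical.set_index("patient_id") if "patient_id" in clinical else clinical
    return pd.DataFrame({
        "sex_m": (df["sex"] == "M").astype(float),
        "age": df["age"].astype(float),
        "stage_ii": (df["stage"] == "II").astype(float),
        "stage_iiia": (df["stage"] == "IIIA").astype(float),
    }, index=df.index)


def load_cohort_files(config: AnalysisConfig):
    counts = {lab: CountMatrix.from_tsv(p) for lab, p in config.counts.items()}
    clin = pd.read_csv(config.clinical)
    if config.outcome is not None:
        out = pd.read_csv(config.outcome)
        clin = clin.merge(out, on="patient_id", how="inner")
    return counts, clin


def _complete_cases(clin: pd.DataFrame) -> pd.DataFrame:
    needed = ["patient_id", "age", "sex", "stage", "dfs_months", "dfs_event"]
    missing = [c for c in needed if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    ok = clin[needed].notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropping %d patients with incomplete covariates/outcome", dropped)
    return clin.loc[ok]


def _analysis_set(expr: ExpressionMatrix, clin: pd.DataFrame, label: str):
    """Patients with surviving libraries AND complete clinical/outcome."""
    ids = [s for s in expr.values.columns if s in set(clin["patient_id"])]
    clin_s = clin.set_index("patient_id").loc[ids].reset_index()
    mirna_block = expr.values[ids].T
    mirna_block.columns = [str(c) for c in mirna_block.columns]
    return ids, mirna_block, clin_s


def cohort_analysis_inputs(cohort, q3_threshold: float = 5.0):
    """Preprocess a (synthetic) cohort into model-ready inputs.

    Returns ``(blocks, outcome, expr)``: the miRNA and clinical predictor
    blocks aligned on the samples surviving the filters, the matching
    outcome, and the normalized expression matrix.
    """
    expr = preprocess_counts(cohort.counts, q3_threshold=q3_threshold)
    ids, mirna_block, clin_s = _analysis_set(expr, cohort.table, "mirna")
    outcome = SurvivalOutcome(clin_s["dfs_months"].to_numpy(),
                              clin_s["dfs_event"].to_numpy().astype(int),
                              clin_s["patient_id"].to_numpy())
    blocks = {"mirna": mirna_block.reset_index(drop=True),
              "clinical": clinical_design(clin_s).reset_index(drop=True)}
    return blocks, outcome, expr


def _run_single_analysis(label: str, counts: CountMatrix, clin: pd.DataFrame,
                         config: AnalysisConfig,
                         expr: ExpressionMatrix | None = None) -> dict:
    if expr is None:
        expr = preprocess_counts(counts, q3_threshold=config.q3_threshold)
    ids, mirna_block, clin_s = _analysis_set(expr, clin, label)
    outcome = SurvivalOutcome(clin_s["dfs_months"].to_numpy(),
                              clin_s["dfs_event"].to_numpy().astype(int),
                              clin_s["patient_id"].to_numpy())
    blocks = {"mirna": mirna_block.reset_index(drop=True),
              "clinical": clinical_design(clin_s).reset_index(drop=True)}
    builder = None
    if config.within_fold_normalization:
        kept = filter_samples(filter_mirnas(counts, config.q3_threshold))
        kept = CountMatrix(kept.values[ids])
        clin_design_full = clinical_design(clin_s).reset_index(drop=True)

        def builder(train_mask, _cm=kept, _cd=clin_design_full):
            tr_cm = CountMatrix(_cm.values.iloc[:, train_mask])
            te_cm = CountMatrix(_cm.values.iloc[:, ~train_mask])
            e_tr, e_te = fold_normalization(tr_cm, te_cm)
            return ({"mirna": e_tr.T.reset_index(drop=True),
                     "clinical": _cd[train_mask].reset_index(drop=True)},
                    {"mirna": e_te.T.reset_index(drop=True),
                     "clinical": _cd[~train_mask].reset_index(drop=True)})

    return _run_model_suite(label, blocks, outcome, expr, config, builder)


def _serialize_coefs(beta: pd.Series) -> dict:
    return {str(k): float(v) for k, v in beta.items() if v != 0.0}


def _run_model_suite(label: str, blocks: dict, outcome: SurvivalOutcome,
                     expr: ExpressionMatrix | None, config: AnalysisConfig,
                     builder=None) -> dict:
    specs = standard_model_specs(tuple(b for b in blocks if b != "clinical"))
    n = len(outcome)
    logger.info("[%s] analysis set: %d patients, %d events, %d miRNAs",
                label, n, int(outcome.event.sum()),
                sum(blocks[b].shape[1] for b in blocks if b != "clinical"))
    report: dict = {
        "label": label,
        "n_patients": n,
        "n_events": int(outcome.event.sum()),
        "median_followup_reverse_km": reverse_km_median_followup(outcome),
        "preprocessing": dict(expr.provenance) if expr is not None else None,
    }
    # full-data fits (coefficient table)
    X_mirna = pd.concat([blocks[b] for b in blocks if b != "clinical"], axis=1)
    X_clin = blocks["clinical"]
    X_comb = pd.concat([X_mirna, X_clin], axis=1)
    pf_comb = np.r_[np.ones(X_mirna.shape[1]), np.zeros(X_clin.shape[1])]
    sel1 = select_lambda_cv(X_mirna, outcome, k=config.k_folds, alpha=config.alpha,
                            seed=config.seed, n_lambdas=config.n_lambdas)
    fit1 = fit_penalized_cox(X_mirna, outcome, lam=sel1.lambda_opt,
                             alpha=config.alpha, strict=False)
    sel2 = select_lambda_cv(X_comb, outcome, k=config.k_folds, alpha=config.alpha,
                            seed=config.seed, penalty_factor=pf_comb,
                            n_lambdas=config.n_lambdas)
    fit2 = fit_penalized_cox(X_comb, outcome, lam=sel2.lambda_opt,
                             alpha=config.alpha, penalty_factor=pf_comb,
                             strict=False)
    fit3 = fit_cox(X_clin, outcome)
    report["models"] = {
        "model1": {"lambda": sel1.lambda_opt, "alpha": config.alpha,
                   "coefficients": _serialize_coefs(fit1.beta),
                   "n_nonzero": fit1.n_nonzero},
        "model2": {"lambda": sel2.lambda_opt, "alpha": config.alpha,
                   "coefficients": _serialize_coefs(fit2.beta),
                   "n_nonzero": fit2.n_nonzero},
        "model3": {"coefficients": {k: float(v) for k, v in fit3.beta.items()},
                   "summary": json.loads(fit3.summary().to_json())},
    }
    # cross-validated evaluation on shared folds
    folds = make_folds(outcome, k=config.k_folds, seed=config.seed)
    report["cv"] = {}
    for mname, spec in specs.items():
        res = cv_statistics(blocks, outcome, spec, k=config.k_folds,
                            seed=config.seed, landmark=config.landmark,
                            alpha=config.alpha, folds=folds,
                            n_lambdas=config.n_lambdas, block_builder=builder)
        report["cv"][mname] = {
            "auc": res["auc"],
            "logrank": res["logrank"],
            "group_sizes": {g: int((res["cvpi"].risk_group == g).sum())
                            for g in ("low", "high")},
            "fold_lambdas": [float(l) for l in res["cvpi"].fold_lambdas],
        }
    # permutation tests (absolute accuracy per model, then added value)
    report["permutation"] = {}
    for mname, spec in specs.items():
        perm = permute_full_null(blocks, outcome, spec, B=config.n_permutations,
                                 seed=config.seed, k=config.k_folds,
                                 landmark=config.landmark, alpha=config.alpha,
                                 redraw_folds=not config.fixed_permutation_folds,
                                 n_lambdas=config.n_lambdas)
        report["permutation"][mname] = {
            "logrank_p": perm["cv_logrank"].p_value,
            "auc_p": perm["cv_auc"].p_value,
            "observed_logrank": perm["cv_logrank"].observed,
            "observed_auc": perm["cv_auc"].observed,
        }
    # added-value nulls keep the observed folds: only the miRNA rows move
    added = added_value_test(X_clin, X_mirna, outcome, B=config.n_permutations,
                             seed=config.seed, k=config.k_folds,
                             landmark=config.landmark, alpha=config.alpha,
                             n_lambdas=config.n_lambdas)
    report["added_value"] = {
        "delta_logrank": added["delta_logrank"].observed,
        "delta_logrank_p": added["delta_logrank"].p_value,
        "delta_auc": added["delta_auc"].observed,
        "delta_auc_p": added["delta_auc"].p_value,
    }
    return report


def run_full_analysis(config: AnalysisConfig,
                      counts: dict[str, CountMatrix] | None = None,
                      clinical: pd.DataFrame | None = None) -> dict:
    """Execute the complete analysis plan; returns the report dict.

    Inputs may be passed in memory (``counts``/``clinical``) or read from
    the paths in ``config``. With two count matrices the plan runs per
    matrix and then combined on the intersection of patients surviving
    both filters, with each matrix normalized separately before the
    blocks are concatenated.
    """
    if counts is None or clinical is None:
        counts, clinical = load_cohort_files(config)
    if not counts:
        raise ValueError("at least one count matrix is required")
    clinical = _complete_cases(clinical)
    report: dict = {
        "provenance": {"config": dataclasses.asdict(config),
                       "cv_deviance": "verweij-van-houwelingen",
                       "lambda_rule": "min"},
        "analyses": {},
    }
    exprs = {}
    for label, cm in counts.items():
        exprs[label] = preprocess_counts(cm, q3_threshold=config.q3_threshold)
        report["analyses"][label] = _run_single_analysis(
            label, cm, clinical, config, expr=exprs[label])
    if len(counts) >= 2:
        shared = set(clinical["patient_id"])
        for e in exprs.values():
            shared &= set(e.values.columns)
        ids = [p for p in clinical["patient_id"] if p in shared]
        logger.info("[combined] %d patients pass all filters", len(ids))
        clin_s = clinical.set_index("patient_id").loc[ids].reset_index()
        outcome = SurvivalOutcome(clin_s["dfs_months"].to_numpy(),
                                  clin_s["dfs_event"].to_numpy().astype(int),
                                  clin_s["patient_id"].to_numpy())
        blocks = {}
        for label, e in exprs.items():
            blk = e.values[ids].T
            blk.columns = [f"{label}_{c}" for c in blk.columns]
            blocks[f"mirna_{label}"] = blk.reset_index(drop=True)
        blocks["clinical"] = clinical_design(clin_s).reset_index(drop=True)
        report["analyses"]["combined"] = _run_model_suite(
            "combined", blocks, outcome, None, config)
        report["analyses"]["combined"]["n_patients_per_block"] = {
            lab: int(e.values.shape[1]) for lab, e in exprs.items()}
    return report


def write_report(report: dict, out_dir) -> None:
    """JSON report plus a human-readable coefficient table per analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    for label, ana in report["analyses"].items():
        rows = {}
        models = ana["models"]
        for pred, c in models["model1"]["coefficients"].items():
            rows.setdefault(pred, {})["model1_coef"] = c
        for pred, c in models["model2"]["coefficients"].items():
            rows.setdefault(pred, {})["model2_coef"] = c
        summ = models["model3"]["summary"]
        for pred in models["model3"]["coefficients"]:
            r = rows.setdefault(pred, {})
            r["model3_coef"] = summ["coef"][pred]
            r["model3_hr"] = summ["hr"][pred]
            r["model3_hr_ci"] = (f"{summ['hr_lower95'][pred]:.2f}-"
                                 f"{summ['hr_upper95'][pred]:.2f}")
            r["model3_p"] = summ["p"][pred]
        tab = pd.DataFrame.from_dict(rows, orient="index").rename_axis("predictor")
        tab.to_csv(out / f"coefficients_{label}.tsv", sep="\t",
                   float_format="%.4g")
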