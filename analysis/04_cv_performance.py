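#!/usr/bin/env python
"""Cross-validated predictive performance of the three models.

Out-of-fold prognostic indices on shared 5-fold splits, median-split CV
Kaplan-Meier curves, and IPCW time-dependent ROC at the 24-month landmark.
Writes per-model statistics to results/cv_performance.json and curve
coordinates (KM per risk group, ROC) to results/curves/ for plotting.
"""

import json

import pandas as pd

from _shared import RESULTS, cohort_and_blocks, parse_args
from mirsurv.crossval import cv_statistics, make_folds, standard_model_specs


def main():
    args = parse_args(__doc__)
    _, blocks, outcome, _ = cohort_and_blocks(args.seed)
    folds = make_folds(outcome, k=5, seed=args.seed)
    curves_dir = RESULTS / "curves"
    curves_dir.mkdir(parents=True, exist_ok=True)

    summary = {"seed": args.seed, "landmark_months": 24, "models": {}}
    for name, spec in standard_model_specs(("mirna",)).items():
        res = cv_statistics(blocks, outcome, spec, seed=args.seed, folds=folds)
        summary["models"][name] = {
            "cv_auc": round(res["auc"], 4),
            "cv_logrank": round(res["logrank"], 4),
            "group_sizes": {g: int((res["cvpi"].risk_group == g).sum())
                            for g in ("low", "high")},
        }
        roc = res["roc"]
        pd.DataFrame({"fp": roc.fp, "tp": roc.tp}).to_csv(
            curves_dir / f"roc_{name}.tsv", sep="\t", index=False)
        km_rows = []
        for grp, c in res["curves"].items():
            for t, s, r in zip(c.times, c.survival, c.at_risk):
                km_rows.append({"group": grp, "months": t, "survival": s,
                                "at_risk": r})
        pd.DataFrame(km_rows).to_csv(curves_dir / f"cv_km_{name}.tsv",
                                     sep="\t", index=False)

    with open(RESULTS / "cv_performance.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
    m = summary["models"]
    print(f"\nFinding: 24-month CV AUCs — miRNA-only {m['model1']['cv_auc']}, "
          f"combined {m['model2']['cv_auc']}, clinical-only "
          f"{m['model3']['cv_auc']}; CV-KM log-rank statistics "
          f"{m['model1']['cv_logrank']}, {m['model2']['cv_logrank']}, "
          f"{m['model3']['cv_logrank']} (significance assessed by "
          f"permutation in the next step).")


if __name__ == "__main__":
    main()
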