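#!/usr/bin/env python
"""Screen miRNA expression against demographic/clinical covariates.

Per-miRNA two-sample Student t-tests with Benjamini-Hochberg adjustment:
males vs females, and advanced stage (II + IIIA) vs stage I. Writes the
full tables to results/associations_sex.tsv and
results/associations_stage.tsv.
"""

import json

from _shared import RESULTS, cohort_and_blocks, parse_args
from mirsurv.association import dichotomize, mirna_covariate_ttests


def main():
    args = parse_args(__doc__)
    cohort, blocks, outcome, expr = cohort_and_blocks(args.seed)
    clin = cohort.clinical.set_index("patient_id").loc[list(expr.values.columns)]

    contrasts = {
        "sex": dichotomize(clin["sex"], ["M"]),
        "stage": dichotomize(clin["stage"], ["II", "IIIA"]),
    }
    summary = {"seed": args.seed}
    for name, labels in contrasts.items():
        tab = mirna_covariate_ttests(expr, labels, contrast_name=name)
        tab = tab.sort_values("p_adj")
        tab.to_csv(RESULTS / f"associations_{name}.tsv", sep="\t",
                   float_format="%.4g")
        n_sig = int((tab["p_adj"] < 0.05).sum())
        summary[name] = {"n_tested": int(len(tab)), "n_significant_fdr05": n_sig,
                         "top_hit": tab.index[0],
                         "top_hit_p_adj": float(tab["p_adj"].iloc[0])}
        print(f"{name}: {n_sig} of {len(tab)} miRNAs at FDR < 0.05; "
              f"top: {tab.index[0]} (adj p = {tab['p_adj'].iloc[0]:.3g})")
    with open(RESULTS / "associations_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print("\nFinding: the generator plants no sex- or stage-linked expression "
          "by default, so FDR-significant hits here reflect the multiplicity "
          "control's behaviour under the null (expected: none or very few).")


if __name__ == "__main__":
    main()
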