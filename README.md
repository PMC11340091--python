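# mirsurv

Prognostic modelling of circulating miRNA-seq with survival outcomes:
from a raw count matrix and a clinical table to penalized Cox signatures,
cross-validated risk stratification, and permutation tests of whether the
biomarkers actually add predictive accuracy.

## The problem

Resected early-stage non-small-cell lung cancer relapses in roughly half
of patients, and circulating microRNAs — measured cell-free in plasma or
inside extracellular vesicles — are candidate non-invasive prognostic
markers. The statistical difficulty is typical of high-dimensional
biomarker studies: a few hundred miRNAs survive count filtering in a
cohort of ~200 patients with ~50 disease-free-survival (DFS) events, so
any signature must be built with penalization, evaluated without
train/test leakage, and compared honestly against the prognostic factors
clinicians already have (age, sex, pathological stage).

`mirsurv` implements that workflow end to end:

1. **Preprocessing** — miRNAs with a third quartile below 5 counts are
   excluded, then samples whose median or first quartile across the
   remaining miRNAs is zero; TMM (trimmed mean of M-values) scaling
   factors; log2-CPM; per-miRNA Blom rank-based inverse-normal scores
   `Φ⁻¹((r − 3/8)/(n + 1/4))`.
2. **Models** — Model 1: elastic-net penalized Cox (`α = 0.9` mixing,
   penalty `λ[α‖β‖₁ + (1−α)/2‖β‖₂²]`, λ by 5-fold CV deviance) on the
   miRNA block; Model 2: miRNAs plus clinical factors (clinical
   unpenalized); Model 3: standard Cox on the clinical factors alone.
   Breslow ties throughout.
3. **Cross-validated evaluation** — out-of-fold prognostic indices x'β
   (each patient scored by a model never trained on them), median-split
   CV Kaplan–Meier curves with their log-rank statistic, and IPCW
   cumulative/dynamic time-dependent ROC at a 24-month landmark.
4. **Permutation inference** — the CV statistics have no textbook null:
   p-values come from re-running the entire CV procedure under
   permutations of the outcome (absolute accuracy) or of the miRNA block
   alone (added value of the miRNAs over the clinical model), with the
   add-one rule `p = (1 + #{null ≥ obs})/(B + 1)`.
5. **Synthetic cohorts** — a generator (NB counts, lognormal library
   sizes, Weibull-baseline proportional hazards, stage/sex/age effects of
   realistic magnitude) makes every stage testable without patient data.

## Worked example

```python
from mirsurv import SimulationConfig, simulate_cohort, AnalysisConfig, run_full_analysis

cohort = simulate_cohort(SimulationConfig(seed=1))   # 200 patients, 2000 miRNAs
config = AnalysisConfig(n_permutations=100, seed=1)
report = run_full_analysis(config, counts={"mirna": cohort.counts},
                           clinical=cohort.table)
ana = report["analyses"]["mirna"]
print(ana["preprocessing"]["n_mirnas_retained"],   # 412
      ana["n_events"],                             # 46
      round(ana["cv"]["model1"]["auc"], 3),        # 0.732
      round(ana["cv"]["model3"]["auc"], 3),        # 0.568
      ana["permutation"]["model1"]["auc_p"],       # 0.0099
      round(ana["added_value"]["delta_auc"], 3),   # 0.123
      ana["added_value"]["delta_auc_p"])           # 0.0099
```

Reading: of 2000 simulated miRNAs, 412 pass the count filter; 173 of 200
libraries survive the sample filter, leaving 46 DFS events. The miRNA-only
signature discriminates 24-month outcomes with a cross-validated AUC of
0.73 (permutation p ≈ 0.01 against AUC = 0.5, B = 100), the clinical-only
model reaches 0.57, and adding the miRNAs to the clinical factors raises
the landmark AUC by 0.12 (added-value permutation p ≈ 0.01) — as it
should, since this cohort was simulated with five truly prognostic miRNAs
independent of stage.

The same steps are available as numbered drivers
(`python analysis/01_simulate_cohort.py --seed 1` … `06_…`), each writing
its tables under `results/`, and as a CLI
(`mirsurv simulate|preprocess|evaluate|permtest|associate|run`).

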