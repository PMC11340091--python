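"""Screen miRNA expression against clinical covariates.

Two-sample Student t-tests (pooled variance; Welch available by flag) of
each miRNA's transformed expression between the levels of a binary
covariate, with Benjamini-Hochberg adjustment across miRNAs within the
contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = ["mirna_covariate_ttests", "dichotomize"]


def dichotomize(values: pd.Series, positive_levels) -> np.ndarray:
    """Binary labels: 1 for the listed levels, 0 otherwise."""
    return values.isin(list(positive_levels)).to_numpy().astype(int)


def mirna_covariate_ttests(expr: ExpressionMatrix | pd.DataFrame,
                           labels, contrast_name: str = "contrast",
                           welch: bool = False) -> pd.DataFrame:
    """Per-miRNA t-test between the two label groups, BH-adjusted.

    ``labels`` are binary (0/1) per sample; the mean difference reported
    is group-1 minus group-0. Both groups need at least two members.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    g1 = labels == 1
    g0 = labels == 0
    if g1.sum() < 2 or g0.sum() < 2:
        raise ValueError("both groups need at least two samples")
    a = values.to_numpy()[:, g1]
    b = values.to_numpy()[:, g0]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "mirna_id": values.index,
        "contrast": contrast_name,
        "mean_diff": a.mean(axis=1) - b.mean(axis=1),
        "t": t,
        "p": p,
        "p_adj": p_adj,
        "n_group1": int(g1.sum()),
        "n_group0": int(g0.sum()),
    }).set_index("mirna_id")
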