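"""IC50 imputation from expression and risk-group sensitivity screening.

Per drug, a ridge regression is trained on a cell-line panel (log-IC50 against
per-gene standardised expression over the gene intersection) and applied to
the cohort, each side standardised with its own per-gene statistics.  The
screen then compares imputed IC50 between the high- and low-risk groups with a
two-sided rank-sum test; a drug passes when the high-risk median is lower and
the p-value clears a stringent threshold (1e-10 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    return (M - mu) / np.where(sd == 0, 1.0, sd)


def impute_ic50(panel_expression: pd.DataFrame, panel_ic50: pd.DataFrame,
                cohort_expression: pd.DataFrame,
                ridge_penalty: float | str = "loo") -> pd.DataFrame:
    """Imputed log-IC50 per cohort sample per drug.

    Parameters
    ----------
    panel_expression : genes x cell lines.
    panel_ic50 : cell lines x drugs, log-IC50.
    cohort_expression : genes x cohort samples.
    ridge_penalty : a fixed penalty, or ``"loo"`` to pick it per drug by
        efficient leave-one-line-out cross-validation.
    """
    shared = panel_expression.index.intersection(cohort_expression.index)
    if len(shared) == 0:
        raise ValueError("empty gene intersection between panel and cohort")
    if len(panel_ic50) < 2:
        raise ValueError("need at least 2 cell lines per drug")
    Xp = _standardize(np.log2(
        panel_expression.loc[shared, panel_ic50.index].to_numpy().T + 1.0))
    Xc = _standardize(np.log2(cohort_expression.loc[shared].to_numpy().T + 1.0))
    out = np.empty((Xc.shape[0], panel_ic50.shape[1]))
    alphas = np.logspace(-2, 4, 13)
    for j, drug in enumerate(panel_ic50.columns):
        y = panel_ic50[drug].to_numpy()
        if ridge_penalty == "loo":
            model = RidgeCV(alphas=alphas)   # efficient LOO by default
        else:
            model = Ridge(alpha=float(ridge_penalty))
        model.fit(Xp, y)
        out[:, j] = model.predict(Xc)
    return pd.DataFrame(out, index=cohort_expression.columns,
                        columns=panel_ic50.columns)


def sensitivity_screen(imputed: pd.DataFrame, group: pd.Series,
                       p_threshold: float = 1e-10) -> pd.DataFrame:
    """Per-drug rank-sum screen for higher sensitivity (lower IC50) in the
    high-risk group.

    Returns a DataFrame (drug, median_high, median_low, p, pass) with passing
    drugs ranked first by ascending p.
    """
    g = group.reindex(imputed.index)
    hi = imputed.loc[g == "high"]
    lo = imputed.loc[g == "low"]
    if hi.empty or lo.empty:
        raise ValueError("both risk groups must be non-empty")
    rows = []
    for drug in imputed.columns:
        a, b = hi[drug].to_numpy(), lo[drug].to_numpy()
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        mh, ml = float(np.median(a)), float(np.median(b))
        rows.append({"drug": drug, "median_high": mh, "median_low": ml,
                     "p": p, "pass": (mh < ml) and (p < p_threshold)})
    out = pd.DataFrame(rows)
    return out.sort_values(["pass", "p"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)
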