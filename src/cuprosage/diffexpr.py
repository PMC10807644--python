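"""Differential screening, ssGSEA immune scoring and TMB scoring.

The panel screen is a two-sided Wilcoxon rank-sum test per gene with
Benjamini-Hochberg control across the tested panel; a gene is selected when
both the raw p-value and its BH-adjusted value fall below their thresholds.
Fold change is computed on group means with a pseudocount of 1, on the log2
scale.  The genome-wide DEG screen adds an absolute log2 fold-change filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1.0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test; exact for small tie-free samples.

    Returns (statistic U, p).  Identical groups give p = 1 under the exact
    convention.
    """
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GeneTestResult:
    gene: str
    statistic: float
    p_value: float
    fdr: float
    log2_fc: float


def wilcoxon_screen(expression: pd.DataFrame, labels: pd.Series,
                    genes=None, alpha: float = 0.05,
                    fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum screen of ``genes`` (default: all rows) for tumour vs normal.

    Returns a DataFrame (gene, statistic, p_value, fdr, log2_fc, selected)
    sorted stably by p-value.  Selection requires p < alpha AND fdr < fdr_alpha.
    """
    genes = list(expression.index) if genes is None else list(genes)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    tumor_cols = labels.index[labels == "tumor"]
    normal_cols = labels.index[labels == "normal"]
    if len(tumor_cols) == 0 or len(normal_cols) == 0:
        raise ValueError("both tumor and normal groups must be non-empty")

    T = expression.loc[genes, tumor_cols].to_numpy()
    N = expression.loc[genes, normal_cols].to_numpy()
    stats_u = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for i in range(len(genes)):
        stats_u[i], pvals[i] = _ranksum_p(T[i], N[i])
    fdr = bh_fdr(pvals)
    lfc = np.log2((T.mean(axis=1) + PSEUDOCOUNT) / (N.mean(axis=1) + PSEUDOCOUNT))
    out = pd.DataFrame({"gene": genes, "statistic": stats_u, "p_value": pvals,
                        "fdr": fdr, "log2_fc": lfc})
    out["selected"] = (out["p_value"] < alpha) & (out["fdr"] < fdr_alpha)
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def deg_screen_genomewide(expression: pd.DataFrame, labels: pd.Series,
                          fdr_alpha: float = 0.05,
                          lfc_min: float = 1.0) -> dict:
    """Genome-wide DEG partition: FDR < fdr_alpha and |log2FC| >= lfc_min.

    Returns dict with the full table plus 'up', 'down' gene lists and counts.
    """
    table = wilcoxon_screen(expression, labels, alpha=1.1, fdr_alpha=fdr_alpha)
    sig = table["fdr"] < fdr_alpha
    up = table.loc[sig & (table["log2_fc"] >= lfc_min), "gene"].tolist()
    down = table.loc[sig & (table["log2_fc"] <= -lfc_min), "gene"].tolist()
    return {"table": table.drop(columns="selected"), "up": up, "down": down,
            "n_up": len(up), "n_down": len(down), "n_deg": len(up) + len(down)}


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray,
                   weight_exponent: float) -> float:
    """Running-sum enrichment score for one sample.

    Genes are ranked descending by expression; the score is the sum over the
    ranked list of the difference between the weighted in-set empirical CDF
    (weights = rank weight |r|^exponent, here the descending rank position
    raised to the exponent) and the uniform out-of-set CDF.
    """
    n = values.size
    order = np.argsort(-values, kind="stable")
    in_ord = in_set[order]
    n_in = int(in_set.sum())
    n_out = n - n_in
    if n_out == 0:
        raise ValueError("gene set covers the whole matrix: out-of-set CDF undefined")
    ranks = np.arange(n, 1 - 1, -1, dtype=float)  # n..1, highest expression first
    w = np.where(in_ord, ranks ** weight_exponent, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea(expression: pd.DataFrame, gene_sets: dict,
           weight_exponent: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA scores, samples x gene sets.

    Gene-set members absent from the matrix are ignored; an empty overlap is
    an error naming the set.  With ``normalize`` the scores are min-max scaled
    to [0, 1] across samples jointly over all sets (the customary cross-sample
    normalisation).
    """
    genes = expression.index
    masks = {}
    for name, members in gene_sets.items():
        mask = np.asarray(genes.isin(set(members)))
        if not mask.any():
            raise ValueError(f"gene set '{name}' has no overlap with the matrix")
        if mask.all():
            raise ValueError(f"gene set '{name}' covers the whole matrix")
        masks[name] = mask
    X = expression.to_numpy()
    out = np.empty((X.shape[1], len(masks)))
    for j in range(X.shape[1]):
        for k, mask in enumerate(masks.values()):
            out[j, k] = _ssgsea_sample(X[:, j], mask, weight_exponent)
    scores = pd.DataFrame(out, index=expression.columns, columns=list(masks))
    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def tmb_score(mutations: pd.DataFrame, genome_mb: float | None = None) -> dict:
    """Tumour mutation burden per sample plus a median high/low split.

    Score = total mutations per sample, divided by ``genome_mb`` when given.
    Ties at the median go to the low group.  Also returns per-gene mutation
    frequencies (fraction of samples with >= 1 mutation) sorted descending.
    """
    counts = mutations.to_numpy()
    if (counts < 0).any():
        raise ValueError("mutation counts must be non-negative")
    score = counts.sum(axis=1).astype(float)
    if genome_mb is not None:
        score = score / genome_mb
    scores = pd.Series(score, index=mutations.index, name="tmb")
    med = float(np.median(score))
    group = pd.Series(np.where(score > med, "high", "low"), index=mutations.index,
                      name="tmb_group")
    degenerate = bool((group == group.iloc[0]).all())
    freq = (mutations > 0).mean(axis=0).sort_values(ascending=False, kind="stable")
    return {"scores": scores, "median": med, "group": group,
            "degenerate_split": degenerate, "gene_frequency": freq}
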