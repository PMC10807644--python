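"""Risk grouping and survival statistics.

Time-horizon ROC with Youden-index cutoff, Kaplan-Meier curves and log-rank
tests, a Cox proportional-hazards fitter (Newton-Raphson on the Breslow
partial likelihood with step-halving), univariate/multivariate independence
analysis, early/late stage-stratified analysis, PCA scores, a nomogram with
Breslow baseline survival and calibration, and restricted 0-10-year C-index
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dnn import harrell_c_index  # noqa: F401  (re-exported surface)


# ---------------------------------------------------------------------------
# time-horizon ROC and Youden cutoff
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def horizon_roc(scores, times, events, horizon: float) -> RocCurve:
    """ROC of the risk score for event-by-horizon status.

    Cases: event within the horizon.  Controls: followed beyond the horizon.
    Samples censored before the horizon are excluded (no IPCW weighting; an
    inverse-probability variant is out of scope of the default path).
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    case = (t <= horizon) & e
    control = t > horizon
    keep = case | control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    fpr, tpr, thr = _sk_roc_curve(case[keep].astype(int), s[keep])
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(horizon=horizon, thresholds=thr, sensitivity=sens,
                    specificity=spec, auc=auc,
                    n_cases=int(case.sum()), n_controls=int(control.sum()))


@dataclass
class RiskGrouping:
    cutoff: float
    group: pd.Series  # 'high' / 'low' per sample


def youden_cutoff(roc: RocCurve) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties resolve to the lower threshold (the more sensitive grouping).  The
    sentinel +inf threshold emitted at the all-negative end is never returned.
    """
    finite = np.isfinite(roc.thresholds)
    if finite.sum() == 0:
        raise ValueError("degenerate ROC curve")
    J = roc.sensitivity + roc.specificity - 1.0
    J = np.where(finite, J, -np.inf)
    best = J.max()
    if not np.isfinite(best):
        raise ValueError("degenerate ROC curve")
    candidates = roc.thresholds[J >= best - 1e-12]
    return float(candidates.min())


def assign_risk_groups(scores: pd.Series, cutoff: float) -> RiskGrouping:
    """high iff score > cutoff."""
    s = pd.Series(scores)
    return RiskGrouping(cutoff=float(cutoff),
                        group=pd.Series(np.where(s > cutoff, "high", "low"),
                                        index=s.index, name="risk_group"))


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(times, events, group=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival step function, overall or per group."""
    t = np.asarray(times, float)
    e = np.asarray(events)
    g = np.asarray(group) if group is not None else np.array(["all"] * len(t))
    out = {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        out[str(label)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return out


def logrank_test(times, events, group) -> dict:
    """Log-rank chi-square test across >= 2 groups (1 df for two groups)."""
    g = pd.Series(group)
    if g.nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(np.asarray(times, float), g.to_numpy(),
                                    np.asarray(events))
    return {"statistic": float(res.test_statistic), "p": float(res.p_value),
            "df": int(g.nunique() - 1)}


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxPHResults:
    params: pd.Series
    se: pd.Series
    llf: float
    llnull: float
    converged: bool
    separation: bool
    n: int
    n_events: int
    ll_path: list

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def conf_int(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame({"HR_lower": np.exp(self.params - z * self.se),
                             "HR_upper": np.exp(self.params + z * self.se)})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index,
                         name="p")

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.params, "HR": self.hazard_ratios,
                            "se": self.se})
        out = out.join(self.conf_int)
        out["p"] = self.pvalues
        return out


class CoxPH:
    """Cox PH model on a covariate DataFrame; ``fit`` returns CoxPHResults."""

    def __init__(self, covariates: pd.DataFrame, times, events):
        X = pd.DataFrame(covariates).astype(float)
        if (X.nunique() <= 1).any():
            bad = list(X.columns[X.nunique() <= 1])
            raise ValueError(f"constant covariates: {bad}")
        self.names = list(X.columns)
        self.X = X.to_numpy()
        t = np.asarray(times, float)
        e = np.asarray(events).astype(float)
        if e.sum() < 1:
            raise ValueError("need at least one event")
        self.t, self.e = t, e

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates: list[str],
                       time_col: str = "time", event_col: str = "event") -> "CoxPH":
        return cls(df[covariates], df[time_col], df[event_col])

    def _ll_grad_hess(self, beta: np.ndarray):
        X, t, e = self.X, self.t, self.e
        eta = X @ beta
        eta = eta - eta.max()
        w = np.exp(eta)
        R = t[None, :] >= t[:, None]
        ev = e.astype(bool)
        Rev = R[ev]
        den = Rev @ w                                    # (D,)
        wX = w[:, None] * X
        num1 = Rev @ wX                                  # (D, p)
        xbar = num1 / den[:, None]
        # the eta shift cancels exactly between the two terms
        ll = float(eta[ev].sum() - np.log(den).sum())
        grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
        # Hessian: -sum_d [ S2/den - xbar xbar^T ]
        p = X.shape[1]
        H = np.zeros((p, p))
        S2 = np.einsum("dj,jk,jl->dkl", Rev.astype(float), wX, X)
        H -= (S2 / den[:, None, None]).sum(axis=0)
        H += np.einsum("dk,dl->kl", xbar, xbar)
        return ll, grad, H

    def fit(self, max_iter: int = 50, tol: float = 1e-9) -> CoxPHResults:
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, H = self._ll_grad_hess(beta)
        llnull = ll
        path = [ll]
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step = -np.linalg.pinv(H) @ grad
            # step-halving: the log-likelihood never decreases
            alpha = 1.0
            for _ in range(30):
                new_ll, new_grad, new_H = self._ll_grad_hess(beta + alpha * step)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    break
                alpha *= 0.5
            beta = beta + alpha * step
            path.append(new_ll)
            if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
                ll, grad, H = new_ll, new_grad, new_H
                converged = True
                break
            ll, grad, H = new_ll, new_grad, new_H
        separation = bool(np.linalg.norm(beta, np.inf) > 15.0)
        if not converged or separation:
            warnings.warn("Cox fit flagged: "
                          + ("non-convergence " if not converged else "")
                          + ("separation" if separation else ""))
        cov = np.linalg.pinv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return CoxPHResults(params=pd.Series(beta, index=self.names, name="coef"),
                            se=pd.Series(se, index=self.names, name="se"),
                            llf=ll, llnull=llnull, converged=converged,
                            separation=separation, n=len(self.t),
                            n_events=int(self.e.sum()), ll_path=path)


def cox_ph_fit(covariates: pd.DataFrame, times, events, **kwargs) -> CoxPHResults:
    return CoxPH(covariates, times, events).fit(**kwargs)


def independence_analysis(risk_score: pd.Series, clinical: pd.DataFrame,
                          covariates: list[str] | None = None,
                          alpha: float = 0.001) -> dict:
    """Univariate Cox per covariate plus one joint multivariate fit.

    The risk score enters alongside the clinical covariates; significance is
    flagged at p < alpha (0.001 by default).
    """
    covariates = covariates or ["age", "gender", "stage", "grade", "T", "M"]
    df = clinical.copy()
    df["risk_score"] = risk_score.reindex(df.index)
    rows = []
    for cov in ["risk_score"] + covariates:
        fit = cox_ph_fit(df[[cov]], df["time"], df["event"])
        s = fit.summary().loc[cov]
        rows.append({"covariate": cov, "analysis": "univariate", **s.to_dict()})
    multi = cox_ph_fit(df[["risk_score"] + covariates], df["time"], df["event"])
    for cov, s in multi.summary().iterrows():
        rows.append({"covariate": cov, "analysis": "multivariate", **s.to_dict()})
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    return {"table": table, "multivariate_fit": multi,
            "risk_independent": bool(
                table.query("covariate == 'risk_score'")["significant"].all())}


def stage_split_analysis(grouping: RiskGrouping, clinical: pd.DataFrame) -> dict:
    """Log-rank of risk groups within early (I-II) and late (III-IV) stages."""
    out = {}
    for name, mask in [("early_I_II", clinical["stage"] <= 2),
                       ("late_III_IV", clinical["stage"] >= 3)]:
        idx = clinical.index[mask]
        if len(idx) == 0:
            warnings.warn(f"empty stratum {name}: skipped")
            out[name] = None
            continue
        g = grouping.group.reindex(idx)
        if g.nunique() < 2:
            warnings.warn(f"single risk group in stratum {name}: skipped")
            out[name] = None
            continue
        out[name] = logrank_test(clinical.loc[idx, "time"],
                                 clinical.loc[idx, "event"], g)
        out[name]["km"] = km_estimate(clinical.loc[idx, "time"],
                                      clinical.loc[idx, "event"], g)
    return out


# ---------------------------------------------------------------------------
# PCA scores
# ---------------------------------------------------------------------------

def pca_scores(X, k: int = 2) -> np.ndarray:
    """First k principal-component scores of the centred data.

    Component signs fixed so each component's largest-magnitude loading is
    positive.
    """
    A = np.asarray(X, float)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    A = A - A.mean(axis=0)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    flip = np.sign(Vt[np.arange(k), np.abs(Vt[:k]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (U[:, :k] * S[:k]) * flip


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

def breslow_baseline_survival(fit: CoxPHResults, X: pd.DataFrame, times,
                              events) -> pd.DataFrame:
    """Breslow estimator of S0(t) at the covariate mean."""
    beta = fit.params.to_numpy()
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    w = np.exp(Xc @ beta)
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    event_times = np.sort(np.unique(t[e]))
    H0 = np.zeros(event_times.size)
    cum = 0.0
    for i, et in enumerate(event_times):
        d = ((t == et) & e).sum()
        at_risk = w[t >= et].sum()
        cum += d / at_risk
        H0[i] = cum
    return pd.DataFrame({"time": event_times, "baseline_survival": np.exp(-H0)})


@dataclass
class NomogramModel:
    fit: CoxPHResults
    reference: pd.Series        # per-covariate value earning 0 points
    scale: float                # points per unit of |beta * (x - ref)|
    mean: pd.Series             # centring used by the linear predictor
    baseline: pd.DataFrame      # S0(t) grid
    horizons: tuple

    def points(self, covariates: pd.Series) -> pd.Series:
        # references sit at the minimal-risk covariate value, so each
        # contribution beta * (x - ref) is non-negative by construction
        beta = self.fit.params
        contrib = beta * (covariates[beta.index] - self.reference)
        return contrib.clip(lower=0.0) * self.scale

    def total_points(self, covariates: pd.Series) -> float:
        return float(self.points(covariates).sum())

    def _s0_at(self, horizon: float) -> float:
        b = self.baseline
        before = b[b["time"] <= horizon]
        return float(before["baseline_survival"].iloc[-1]) if len(before) else 1.0

    def predict_survival(self, covariates: pd.Series) -> dict[float, float]:
        """S(t|x) = S0(t)^exp(beta'(x - mean)) at each horizon."""
        beta = self.fit.params
        lp = float((beta * (covariates[beta.index] - self.mean)).sum())
        return {h: self._s0_at(h) ** np.exp(lp) for h in self.horizons}


def build_nomogram(fit: CoxPHResults, X: pd.DataFrame, times, events,
                   horizons: tuple = (1.0, 3.0, 5.0)) -> NomogramModel:
    """Point scales per covariate (widest-range covariate spans 0-100) and
    total-points -> survival maps at the horizons via the Breslow baseline."""
    if not fit.converged:
        warnings.warn("building a nomogram on a non-converged Cox fit")
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    if e.sum() and max(horizons) > t[e].max():
        raise ValueError("horizon beyond last event time")
    beta = fit.params
    # reference = covariate value at minimal risk contribution
    ref = pd.Series({c: (X[c].min() if beta[c] > 0 else X[c].max())
                     for c in beta.index})
    ranges = pd.Series({c: abs(beta[c]) * (X[c].max() - X[c].min())
                        for c in beta.index})
    widest = ranges.max()
    scale = 100.0 / widest if widest > 0 else 1.0
    baseline = breslow_baseline_survival(fit, X, times, events)
    return NomogramModel(fit=fit, reference=ref, scale=scale,
                         mean=X.mean(), baseline=baseline, horizons=horizons)


def nomogram_predict(model: NomogramModel, covariates: pd.Series) -> dict:
    return {"points": model.points(covariates),
            "total_points": model.total_points(covariates),
            "survival": model.predict_survival(covariates)}


def calibration(model: NomogramModel, X: pd.DataFrame, times, events,
                horizon: float, n_bins: int = 3) -> pd.DataFrame:
    """Predicted vs observed-KM survival at the horizon, binned by prediction."""
    pred = np.array([model.predict_survival(X.loc[i])[horizon] for i in X.index])
    order = np.argsort(pred, kind="stable")
    bins = np.array_split(order, n_bins)
    t = np.asarray(times, float)
    e = np.asarray(events)
    rows = []
    for b in bins:
        if len(b) == 0:
            continue
        kmf = KaplanMeierFitter().fit(t[b], e[b])
        rows.append({"predicted": float(pred[b].mean()),
                     "observed": float(kmf.predict(horizon)),
                     "n": len(b)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restricted C-index curve
# ---------------------------------------------------------------------------

def restricted_c_index(scores, times, events, tau: float) -> float | None:
    """Harrell C over pairs whose earlier (event) time is <= tau."""
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    earlier = (t[:, None] < t[None, :]) & e[:, None] & (t[:, None] <= tau)
    n_pairs = earlier.sum()
    if n_pairs == 0:
        return None
    conc = (s[:, None] > s[None, :]) & earlier
    ties = (s[:, None] == s[None, :]) & earlier
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)


def c_index_curve(predictors: pd.DataFrame, times, events,
                  year_grid=None) -> pd.DataFrame:
    """Per-predictor restricted C-index over a 0-10-year grid.

    Years with no usable pairs yield NaN (flagged gap values).
    """
    grid = np.arange(1.0, 11.0) if year_grid is None else np.asarray(year_grid, float)
    rows = {}
    for name in predictors.columns:
        vals = []
        for tau in grid:
            c = restricted_c_index(predictors[name], times, events, tau)
            vals.append(np.nan if c is None else c)
        rows[name] = vals
    out = pd.DataFrame(rows, index=pd.Index(grid, name="year"))
    return out


# ---------------------------------------------------------------------------
# Lasso-selected Cox comparator
# ---------------------------------------------------------------------------

def lasso_cox_select(X: pd.DataFrame, times, events, n_folds: int = 5,
                     seed: int = 0) -> list[str]:
    """L1-penalised Cox variable selection with cross-validated penalty.

    Backed by the elastic-net Cox path (l1_ratio = 1) with the penalty chosen
    by K-fold cross-validated partial likelihood; returns the selected
    covariate names.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(np.asarray(events).astype(bool), np.asarray(times, float))
    Xv = X.to_numpy()
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01)
    path.fit(Xv, y)
    alphas = path.alphas_
    from sksurv.metrics import concordance_index_censored
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(alphas))
    ev = np.asarray(events).astype(bool)
    tv = np.asarray(times, float)
    for tr, te in kf.split(Xv):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        m.fit(Xv[tr], y[tr])
        for i, a in enumerate(alphas):
            pred = m.predict(Xv[te], alpha=a)
            if np.ptp(pred) == 0:
                continue  # all-zero model: no discrimination
            scores[i] += concordance_index_censored(ev[te], tv[te], pred)[0]
    best = alphas[int(np.argmax(scores))]
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[best])
    final.fit(Xv, y)
    coefs = final.coef_.ravel()
    return [c for c, b in zip(X.columns, coefs) if abs(b) > 1e-10]
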