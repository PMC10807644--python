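"""ROC/Youden, KM/log-rank, Cox PH, PCA, nomogram and C-index curves."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

import cuprosage as cp


# --- horizon ROC ------------------------------------------------------------

def test_roc_perfect_and_null():
    t = np.array([0.5] * 10 + [3.0] * 10)
    e = np.array([1] * 10 + [0] * 10)
    s = (t <= 1.0).astype(float)         # score = case indicator
    roc = cp.horizon_roc(s, t, e, 1.0)
    assert roc.auc == pytest.approx(1.0)

    rng = np.random.default_rng(0)
    s = rng.normal(size=2000)
    t = rng.exponential(2.0, size=2000) + 1e-3
    e = np.ones(2000, dtype=int)
    roc = cp.horizon_roc(s, t, e, 1.0)
    assert roc.auc == pytest.approx(0.5, abs=0.05)


def test_roc_auc_equals_mann_whitney_identity():
    """8-sample worked instance: AUC = U / (n1 * n2) by pair enumeration."""
    s = np.array([0.1, 0.9, 0.4, 0.7, 0.2, 0.8, 0.35, 0.6])
    t = np.array([0.5, 0.4, 0.8, 0.6, 2.0, 3.0, 2.5, 4.0])
    e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    roc = cp.horizon_roc(s, t, e, 1.0)
    cases, controls = s[:4], s[4:]
    u = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    assert roc.auc == pytest.approx(u / 16.0)
    # stored curve integrates to the reported AUC
    order = np.argsort(1.0 - roc.specificity)
    assert np.trapezoid(roc.sensitivity[order],
                        (1.0 - roc.specificity)[order]) == pytest.approx(roc.auc)


def test_roc_excludes_censored_before_horizon_and_errors():
    t = np.array([0.5, 0.6, 2.0, 3.0])
    e = np.array([0, 1, 0, 0])           # first sample censored early
    roc = cp.horizon_roc([1.0, 2.0, 0.5, 0.1], t, e, 1.0)
    assert roc.n_cases == 1 and roc.n_controls == 2
    with pytest.raises(ValueError):
        cp.horizon_roc([1.0, 2.0], [2.0, 3.0], [0, 0], 1.0)


def test_youden_matches_exhaustive_scan():
    s = np.array([0.1, 0.2, 0.45, 0.5, 0.7, 0.9])
    case = np.array([0, 0, 1, 0, 1, 1])
    t = np.where(case, 0.5, 2.0)
    roc = cp.horizon_roc(s, t, np.ones(6, int), 1.0)
    cut = cp.youden_cutoff(roc)
    best_j, best_thr = -np.inf, None
    for thr in np.unique(s):             # exhaustive threshold scan
        sens = ((s >= thr) & (case == 1)).sum() / case.sum()
        spec = ((s < thr) & (case == 0)).sum() / (1 - case).sum()
        j = sens + spec - 1
        if j > best_j - 1e-12:
            if j > best_j + 1e-12 or thr < best_thr:
                best_j, best_thr = max(best_j, j), thr
    assert cut == pytest.approx(best_thr)
    groups = cp.assign_risk_groups(pd.Series(s), cut)
    assert (groups.group == np.where(s > cut, "high", "low")).all()


def test_youden_perfectly_separable_returns_lowest_separating_threshold():
    s = np.array([0.1, 0.2, 0.8, 0.9])
    t = np.array([5.0, 5.0, 0.5, 0.5])
    e = np.array([0, 0, 1, 1])
    roc = cp.horizon_roc(s, t, e, 1.0)
    assert cp.youden_cutoff(roc) == pytest.approx(0.8)


# --- KM and log-rank --------------------------------------------------------

def test_km_without_censoring_is_empirical_survival():
    t = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
    e = np.ones(5, int)
    km = cp.km_estimate(t, e)["all"]
    for time, surv in zip(km["time"], km["survival"]):
        assert surv == pytest.approx((t > time).mean())


def test_logrank_identical_groups_and_hand_tabulation():
    t = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
    e = np.ones(10, int)
    g = np.array(["a"] * 5 + ["b"] * 5)
    res = cp.logrank_test(t, e, g)
    assert res["statistic"] == pytest.approx(0.0, abs=1e-10)
    assert res["p"] == pytest.approx(1.0)

    # 10-subject two-group fixture vs explicit O-E tabulation
    t = np.array([1, 2, 3, 4, 4, 2, 5, 6, 7, 8], dtype=float)
    e = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1, 1])
    g = np.array(["a"] * 5 + ["b"] * 5)
    O = E = V = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n, n1 = at_risk.sum(), (at_risk & (g == "a")).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & (g == "a")).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    expect = (O - E) ** 2 / V
    res = cp.logrank_test(t, e, g)
    assert res["statistic"] == pytest.approx(expect)
    with pytest.raises(ValueError):
        cp.logrank_test(t, e, np.array(["a"] * 10))


# --- Cox PH -----------------------------------------------------------------

def test_cox_single_binary_covariate_matches_1d_likelihood_scan():
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 1, 0, 1, 1])

    def neg_pl(beta):   # explicit risk-set enumeration
        ll = 0.0
        for i in range(6):
            if e[i]:
                den = sum(np.exp(beta * x[j]) for j in range(6) if t[j] >= t[i])
                ll += beta * x[i] - np.log(den)
        return -ll

    scan = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                    options={"xatol": 1e-10})
    fit = cp.cox_ph_fit(pd.DataFrame({"x": x}), t, e)
    assert fit.params["x"] == pytest.approx(scan.x, abs=1e-6)
    assert fit.converged


def test_cox_loglik_never_decreases_and_agrees_with_lifelines(small_cohort):
    clin = small_cohort.clinical
    X = clin[["age", "stage", "grade"]]
    fit = cp.cox_ph_fit(X, clin["time"], clin["event"])
    diffs = np.diff(fit.ll_path)
    assert (diffs >= -1e-9).all()

    cph = CoxPHFitter()
    df = X.copy()
    df["T"], df["E"] = clin["time"], clin["event"]
    cph.fit(df, duration_col="T", event_col="E")
    assert fit.params.to_numpy() == pytest.approx(
        cph.params_.to_numpy(), abs=1e-4)
    assert fit.se.to_numpy() == pytest.approx(
        cph.standard_errors_.to_numpy(), abs=1e-4)
    # invariant: HR = exp(coef), CI ordered
    assert np.allclose(fit.hazard_ratios, np.exp(fit.params))
    ci = fit.conf_int
    assert (ci["HR_upper"] >= ci["HR_lower"]).all()


def test_cox_null_covariate_near_zero(rng):
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(5.0, size=n) + 1e-3
    e = np.ones(n, int)
    fit = cp.cox_ph_fit(pd.DataFrame({"x": x}), t, e)
    assert abs(fit.params["x"]) < 0.15
    assert fit.pvalues["x"] > 0.01


def test_cox_rejects_constant_covariate():
    with pytest.raises(ValueError):
        cp.cox_ph_fit(pd.DataFrame({"c": [1.0, 1.0, 1.0]}),
                      [1, 2, 3], [1, 1, 0])


def test_independence_analysis_flags_risk_score(small_cohort):
    clin = small_cohort.clinical
    res = cp.independence_analysis(small_cohort.true_risk, clin)
    tab = res["table"]
    uni = tab.query("analysis == 'univariate' and covariate == 'risk_score'")
    multi = tab.query("analysis == 'multivariate' and covariate == 'risk_score'")
    assert uni["significant"].item() and multi["significant"].item()
    # the no-link gender covariate mirrors the non-prognostic finding
    guni = tab.query("analysis == 'univariate' and covariate == 'gender'")
    assert not guni["significant"].item()


def test_stage_split_detects_effect_in_both_strata(small_cohort):
    clin = small_cohort.clinical
    med = small_cohort.true_risk.median()
    grouping = cp.assign_risk_groups(small_cohort.true_risk, med)
    res = cp.stage_split_analysis(grouping, clin)
    for key in ("early_I_II", "late_III_IV"):
        assert res[key] is not None
        assert res[key]["p"] < 0.05


# --- PCA --------------------------------------------------------------------

def test_pca_line_and_eigen_oracle_and_duplicates():
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    sc = cp.pca_scores(line, k=1)
    assert np.var(sc[:, 0]) / np.var(line - line.mean(0), axis=0).sum() \
        == pytest.approx(1.0 / 3.0 * 3.0, abs=1e-10)

    X = np.array([[1.0, 2.0, 1.5], [2.0, 1.0, 0.5], [3.0, 4.0, 2.5]])
    C = np.cov((X - X.mean(0)).T, bias=False)
    w, v = np.linalg.eigh(C)
    sc = cp.pca_scores(X, k=2)
    expect = (X - X.mean(0)) @ v[:, ::-1][:, :2]
    for j in range(2):   # compare up to the fixed sign convention
        assert np.allclose(np.abs(sc[:, j]), np.abs(expect[:, j]), atol=1e-8)

    Xd = np.vstack([X, X[0]])
    sd = cp.pca_scores(Xd, k=2)
    assert np.allclose(sd[0], sd[3])
    with pytest.raises(ValueError):
        cp.pca_scores(line, k=3)


# --- nomogram ---------------------------------------------------------------

def _fit_cohort_cox(cohort):
    clin = cohort.clinical
    X = clin[["age", "stage", "grade", "T", "M"]].astype(float).copy()
    X["risk_score"] = cohort.true_risk
    fit = cp.cox_ph_fit(X, clin["time"], clin["event"])
    return X, fit


def test_nomogram_single_binary_covariate_closed_form():
    rng = np.random.default_rng(4)
    n = 200
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(1.0 / (0.2 * np.exp(0.9 * x))) + 1e-4
    e = np.ones(n, int)
    X = pd.DataFrame({"x": x})
    fit = cp.cox_ph_fit(X, t, e)
    nom = cp.build_nomogram(fit, X, t, e, horizons=(1.0,))
    pts = [nom.total_points(pd.Series({"x": v})) for v in (0.0, 1.0)]
    assert sorted(pts) == pytest.approx([0.0, 100.0])
    # closed form: S(t|x) = S0(t)^exp(beta (x - xbar))
    s0 = nom._s0_at(1.0)
    beta = fit.params["x"]
    for v in (0.0, 1.0):
        expect = s0 ** np.exp(beta * (v - x.mean()))
        assert nom.predict_survival(pd.Series({"x": v}))[1.0] == \
            pytest.approx(expect)


def test_nomogram_monotone_and_orders_risk_exemplars(small_cohort):
    X, fit = _fit_cohort_cox(small_cohort)
    clin = small_cohort.clinical
    nom = cp.build_nomogram(fit, X, clin["time"], clin["event"])
    hi = X.loc[small_cohort.true_risk.idxmax()]
    lo = X.loc[small_cohort.true_risk.idxmin()]
    s_hi = nom.predict_survival(hi)
    s_lo = nom.predict_survival(lo)
    for h in (1.0, 3.0, 5.0):
        assert s_hi[h] < s_lo[h]
    assert nom.total_points(hi) > nom.total_points(lo)
    # more total points -> lower predicted survival at every horizon
    order = np.argsort([nom.total_points(X.loc[i]) for i in X.index])
    surv = np.array([nom.predict_survival(X.loc[i])[5.0] for i in X.index])
    assert (np.diff(surv[order]) <= 1e-9).all()


def test_nomogram_calibration_table(small_cohort):
    X, fit = _fit_cohort_cox(small_cohort)
    clin = small_cohort.clinical
    nom = cp.build_nomogram(fit, X, clin["time"], clin["event"])
    cal = cp.calibration(nom, X, clin["time"], clin["event"], horizon=3.0)
    assert len(cal) == 3
    assert ((cal["predicted"] >= 0) & (cal["predicted"] <= 1)).all()
    assert ((cal["observed"] >= 0) & (cal["observed"] <= 1)).all()
    # predictions track observation within a loose calibration band
    assert (cal["predicted"] - cal["observed"]).abs().max() < 0.25


def test_nomogram_rejects_horizon_beyond_follow_up(small_cohort):
    X, fit = _fit_cohort_cox(small_cohort)
    clin = small_cohort.clinical
    with pytest.raises(ValueError):
        cp.build_nomogram(fit, X, clin["time"], clin["event"],
                          horizons=(clin["time"].max() + 100.0,))


# --- restricted C-index curve ----------------------------------------------

def test_cindex_curve_boundary_equals_global_and_perfect_is_one(small_cohort):
    clin = small_cohort.clinical
    s = small_cohort.true_risk
    tau_max = clin["time"].max()
    c_global = cp.harrell_c_index(s, clin["time"], clin["event"])
    c_restr = cp.restricted_c_index(s, clin["time"], clin["event"], tau_max)
    assert c_restr == pytest.approx(c_global)

    t = np.arange(1.0, 13.0)
    e = np.ones(12, int)
    curve = cp.c_index_curve(pd.DataFrame({"perfect": -t}), t, e,
                             year_grid=np.arange(1.0, 11.0))
    assert np.allclose(curve["perfect"].dropna(), 1.0)


def test_cindex_curve_matches_bruteforce_on_12_subjects(rng):
    s = rng.normal(size=12)
    t = rng.exponential(4.0, size=12) + 0.1
    e = rng.integers(0, 2, size=12)
    e[:3] = 1
    grid = np.arange(1.0, 11.0)
    curve = cp.c_index_curve(pd.DataFrame({"s": s}), t, e, year_grid=grid)
    for tau in grid:
        num = den = 0.0
        for i in range(12):
            for j in range(12):
                if e[i] == 1 and t[i] < t[j] and t[i] <= tau:
                    den += 1
                    num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        got = curve.loc[tau, "s"]
        if den == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(num / den)


# --- lasso comparator -------------------------------------------------------

def test_lasso_cox_selects_signal_genes(small_cohort):
    spec = small_cohort.spec
    clin = small_cohort.clinical
    genes = spec.panel_genes
    X = np.log2(small_cohort.expression.loc[genes, clin.index].T + 1)
    chosen = cp.lasso_cox_select(X, clin["time"], clin["event"], seed=0)
    assert set(genes[: spec.n_signal_genes]) <= set(chosen)
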