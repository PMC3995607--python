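"""The outcome-statistics battery against hand-computed and brute-force oracles."""
import numpy as np
import pandas as pd
import pytest

from pulmopet import rp_statistics as rps
from pulmopet import synthetic_data as synth


# ---------------------------------------------------------------- association
def test_mann_whitney_identical_groups():
    df = pd.DataFrame({"age": list(range(20)) * 2,
                       "symptomatic": [0] * 20 + [1] * 20})
    r = rps.association_tests(df, "age", kind="continuous")
    assert r.p_value > 0.99


def test_yates_corrected_chi2_on_gender_table():
    """2x2 gender-by-outcome table: Yates statistic 0.212, p ~ 0.65."""
    rows = [("male", 1)] * 35 + [("male", 0)] * 25 + [("female", 1)] * 26 + [("female", 0)] * 14
    df = pd.DataFrame(rows, columns=["sex", "symptomatic"])
    r = rps.association_tests(df, "sex", kind="categorical")
    assert r.statistic == pytest.approx(0.212, abs=0.001)
    assert r.p_value == pytest.approx(0.65, abs=0.01)
    assert r.df == 1


def test_perfect_association_and_zero_expected_cell():
    rows = [("a", 1)] * 50 + [("b", 0)] * 50
    df = pd.DataFrame(rows, columns=["grp", "symptomatic"])
    r = rps.association_tests(df, "grp", kind="categorical")
    assert r.p_value < 1e-10
    df_bad = pd.DataFrame({"grp": pd.Categorical(["a"] * 10, categories=["a", "b"]),
                           "symptomatic": [0, 1] * 5})
    with pytest.raises(ValueError, match="merge"):
        rps.association_tests(df_bad, "grp", kind="categorical")


# ------------------------------------------------------------------- logistic
def test_odds_ratio_and_ci_are_exp_of_coefficient():
    df = synth.simulate_cohort(synth.CohortConfig(n_patients=400, seed=3))
    fit = rps.fit_logistic(df, ["suv_95", "age"])
    for term in fit.terms:
        assert fit.odds_ratios.loc[term, "or"] == pytest.approx(np.exp(fit.coef[term]))
        assert fit.odds_ratios.loc[term, "ci_low"] == pytest.approx(
            np.exp(fit.coef[term] - 1.96 * fit.se[term]))
        assert fit.odds_ratios.loc[term, "ci_high"] == pytest.approx(
            np.exp(fit.coef[term] + 1.96 * fit.se[term]))
    assert 0 <= fit.nagelkerke_r2 <= 1


def test_null_covariate_gives_unit_odds_ratio():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=200),
                       "symptomatic": rng.integers(0, 2, 200)})
    fit = rps.fit_logistic(df, ["x"])
    assert fit.coef["x"] == pytest.approx(0.0, abs=3 * fit.se["x"])
    lo, hi = fit.odds_ratios.loc["x", ["ci_low", "ci_high"]]
    assert lo < 1.0 < hi


def test_complete_separation_raises_named_error():
    x = np.linspace(-2, 2, 40)
    df = pd.DataFrame({"x": x, "symptomatic": (x > 0).astype(int)})
    with pytest.raises(rps.ModelFitError):
        rps.fit_logistic(df, ["x"])


def test_nagelkerke_hand_case_and_bounds():
    # n = 4, LL0 = 4*ln(0.5), LL1 = 2*ln(0.5): Cox-Snell 0.5 over max 0.75
    assert rps.nagelkerke_r2(-1.3863, -2.7726, 4) == pytest.approx(2 / 3, abs=1e-4)
    assert rps.nagelkerke_r2(-5.0, -5.0, 10) == 0.0
    assert rps.nagelkerke_r2(-1e-9, -50.0, 100) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError, match="null"):
        rps.nagelkerke_r2(-6.0, -5.0, 10)


# ----------------------------------------------------------------------- Holm
def test_holm_stepdown_hand_example():
    res = rps.holm_adjust([0.10, 0.02, 0.0057, 0.013, 0.0061, 0.0049], alpha=0.05)
    assert res.n_rejected == 5
    assert not res.rejected[0]          # only the 0.10 entry survives
    assert rps.holm_adjust([1.0] * 6).n_rejected == 0
    single = rps.holm_adjust([0.04])
    assert single.rejected[0]


def test_holm_adjusted_monotone_and_above_raw():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=12)
    res = rps.holm_adjust(p)
    assert np.all(res.adjusted >= p)
    order = np.argsort(p)
    assert np.all(np.diff(res.adjusted[order]) >= -1e-12)


# ------------------------------------------------------------------------ ROC
def test_auc_small_cases_and_perfect_separation():
    r = rps.roc_delong_youden([1, 2, 3, 4], [0, 0, 1, 1])
    assert r.auc == 1.0
    assert r.youden_j == pytest.approx(1.0)
    assert rps.roc_delong_youden([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75


def test_auc_equals_pairwise_concordance_brute_force(rng):
    for _ in range(20):
        n = int(rng.integers(10, 60))
        scores = rng.normal(size=n).round(1)    # rounding forces ties
        y = rng.integers(0, 2, n).astype(bool)
        if y.all() or not y.any():
            continue
        pos, neg = scores[y], scores[~y]
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                         for a in pos for b in neg])
        assert rps.auc_mann_whitney(scores, y) == pytest.approx(brute)


def test_constant_scores_flagged_not_fabricated():
    with pytest.warns(UserWarning, match="constant"):
        r = rps.roc_delong_youden([1.0] * 10, [0, 1] * 5)
    assert r.auc == 0.5
    assert not r.ci_defined


def test_youden_tie_breaks_toward_specificity():
    # scores 1/2 with outcome balanced: J = 0 at every cut; pick the specific one
    r = rps.roc_delong_youden([1, 2, 1, 2], [0, 0, 1, 1])
    assert r.youden_specificity >= r.youden_sensitivity


# ------------------------------------------------------------------ partition
def test_or_rule_recovered_noise_free(rng):
    n = 500
    suv = rng.uniform(0.5, 1.6, n)
    v30 = rng.uniform(5.0, 45.0, n)
    df = pd.DataFrame({"suv_95": suv, "v30": v30,
                       "symptomatic": ((suv > 1.0) | (v30 > 25.0)).astype(int)})
    tree = rps.recursive_partition(df)
    by_var = {s.variable: s.threshold for s in tree.splits}
    assert set(by_var) == {"suv_95", "v30"}

    # a cutpoint is identifiable only up to the gap between the points whose
    # class it alone determines (the other OR branch masks the rest)
    def gap(values, true_cut, constrained):
        v = values[constrained]
        return v[v > true_cut].min() - v[v <= true_cut].max()

    assert abs(by_var["suv_95"] - 1.0) <= gap(suv, 1.0, v30 <= 25.0)
    assert abs(by_var["v30"] - 25.0) <= gap(v30, 25.0, suv <= 1.0)
    assert tree.sensitivity == pytest.approx(1.0)
    assert tree.specificity == pytest.approx(1.0)


def test_single_class_data_gives_single_leaf(rng):
    df = pd.DataFrame({"suv_95": rng.uniform(0.5, 1.5, 30),
                       "v30": rng.uniform(5, 40, 30), "symptomatic": 0})
    tree = rps.recursive_partition(df)
    assert tree.root.is_leaf
    assert not tree.root.prediction


def test_thresholds_lie_strictly_between_observed_values(cohort100):
    tree = rps.recursive_partition(cohort100)
    for s in tree.splits:
        vals = np.sort(cohort100[s.variable].unique())
        assert vals.min() < s.threshold < vals.max()
        assert s.threshold not in vals


# ------------------------------------------------------------------- survival
def test_km_hand_product_limit_and_median():
    df = pd.DataFrame({"suv_95": [1.0, 1.0, 1.0], "time_days": [1.0, 2.0, 3.0],
                       "event": [1, 1, 1]})
    res = rps.km_fit(df, boundaries=(-1.0, -0.5))     # single (upper) stratum
    (stratum,) = res.strata
    np.testing.assert_allclose(stratum.timeline, [0, 1, 2, 3])
    np.testing.assert_allclose(stratum.survival, [1, 2 / 3, 1 / 3, 0])
    assert stratum.median == 2.0


def test_km_no_events_survival_one_median_absent():
    df = pd.DataFrame({"suv_95": [1.0] * 5, "time_days": [10.0] * 5, "event": [0] * 5})
    res = rps.km_fit(df, boundaries=(-1.0, -0.5))
    (stratum,) = res.strata
    assert np.all(stratum.survival == 1.0)
    assert stratum.median is None
    assert len(stratum.censor_times) == 5


def test_km_without_censoring_matches_empirical_survival(rng):
    t = rng.exponential(50, 200).round(1) + 0.1
    df = pd.DataFrame({"suv_95": 1.0, "time_days": t, "event": 1})
    res = rps.km_fit(df, boundaries=(-1.0, -0.5))
    (s,) = res.strata
    for time, surv in zip(s.timeline, s.survival):
        assert surv == pytest.approx((t > time).mean())


def test_cox_hr_is_exp_of_coefficient_and_zero_variance_pinned():
    df = synth.simulate_cohort(synth.CohortConfig(n_patients=300, seed=6))
    df["flat"] = 1.0
    fit = rps.cox_fit(df, ["suv_95", "flat"])
    assert fit.hazard_ratios.loc["suv_95", "hr"] == pytest.approx(
        np.exp(fit.coef["suv_95"]))
    assert fit.coef["flat"] == 0.0
    assert fit.hazard_ratios.loc["flat", "hr"] == 1.0
    assert fit.p_values["flat"] == 1.0


@pytest.mark.filterwarnings("ignore::Warning")
def test_cox_monotone_likelihood_raises():
    # all events in one level of a binary covariate
    df = pd.DataFrame({"x": [1.0] * 20 + [0.0] * 20,
                       "time_days": np.r_[np.linspace(5, 100, 20),
                                          np.full(20, 183.0)],
                       "event": [1] * 20 + [0] * 20})
    with pytest.raises(rps.ModelFitError):
        rps.cox_fit(df, ["x"])


def test_tercile_boundaries_empirical_vs_pinned():
    vals = np.linspace(0.5, 2.0, 99)
    lo, hi = rps.tercile_boundaries(vals)
    assert lo == pytest.approx(np.percentile(vals, 100 / 3))
    assert rps.tercile_boundaries(vals, paper_compat=True) == (0.99, 1.2)


# ------------------------------------------------------------------ selection
def test_single_strong_candidate_is_retained():
    df = synth.simulate_cohort(synth.CohortConfig(n_patients=1000, seed=12))
    xs = synth.design_columns(df, synth.CohortConfig(n_patients=1000, seed=12))
    sel = rps.backward_aic_select(xs, ["x_suv_95"], model_family="logistic")
    assert sel.selected_terms == ("x_suv_95",)


def test_pure_noise_candidates_mostly_eliminated(rng):
    n = 2000
    df = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(5)})
    df["symptomatic"] = rng.integers(0, 2, n)
    sel = rps.backward_aic_select(df, [f"n{i}" for i in range(5)])
    assert len(sel.selected_terms) <= 2   # ~15.7% false-keep rate per term
    assert sel.fit is None or len(sel.selected_terms) > 0


def test_cox_selection_keeps_active_terms():
    cfg = synth.CohortConfig(n_patients=1500, seed=21)
    df = synth.design_columns(synth.simulate_cohort(cfg), cfg)
    sel = rps.backward_aic_select(df, ["x_suv_95", "x_age", "x_v30"],
                                  model_family="cox")
    assert set(sel.selected_terms) == {"x_suv_95", "x_age", "x_v30"}


# ------------------------------------------------------------------ agreement
def test_identical_readers_give_zero_limits():
    readings = pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.0, 2.0, 3.0]})
    res = rps.bland_altman_loa(readings)
    assert res.limits_of_agreement_pct == (0.0, 0.0)


def test_two_by_two_hand_anova():
    """Deviations are -/+0.9901%; MS_within = SS/(N-k) gives LoA +/-2.744%."""
    res = rps.bland_altman_loa(pd.DataFrame([[100.0, 102.0], [50.0, 51.0]]))
    assert res.mean_deviation_pct == pytest.approx(0.0, abs=1e-12)
    dev = np.abs(res.deviations_pct.to_numpy())
    np.testing.assert_allclose(dev, 100 / 101, rtol=1e-9)
    assert res.within_subject_sd_pct == pytest.approx((100 / 101) * np.sqrt(2))
    assert res.loa_halfwidth_pct == pytest.approx(1.96 * (100 / 101) * np.sqrt(2))


def test_single_reading_subjects_excluded_with_warning():
    readings = pd.DataFrame([[1.0, 1.1], [2.0, np.nan], [3.0, 3.1]])
    with pytest.warns(UserWarning, match="single reading"):
        res = rps.bland_altman_loa(readings)
    assert res.n_subjects == 2
    with pytest.raises(ValueError, match="> 0"):
        rps.bland_altman_loa(pd.DataFrame([[1.0, -1.0], [2.0, 2.1]]))
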