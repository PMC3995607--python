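"""Phantom and cohort generators: determinism, fidelity, calibration."""
import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from pulmopet import rp_statistics as rps
from pulmopet import synthetic_data as synth


def test_constant_lung_field_truth_panel():
    ph = synth.generate_phantom(synth.PhantomSpec(
        grid_shape=(64, 64, 64), seed=0,
        lung_suv_distribution={"name": "constant", "value": 0.7},
        include_cardiac_spillover=False, include_tumor=False,
        include_diaphragm_coldspot=False))
    s = ph.truth.suv_summary
    assert s.mean == pytest.approx(0.7)
    assert s.sd == pytest.approx(0.0, abs=1e-12)
    assert s.p80 == s.p90 == s.p95 == s.max == pytest.approx(0.7)


def test_designed_p95_recovered_in_truth_panel(default_phantom):
    truth = default_phantom.truth
    assert truth.suv_summary.n_voxels >= 10 ** 5
    assert truth.suv_summary.p95 == pytest.approx(1.20, abs=0.02)


def test_same_spec_same_seed_is_bit_identical():
    spec = synth.PhantomSpec(grid_shape=(64, 64, 64), seed=11)
    a = synth.generate_phantom(spec)
    b = synth.generate_phantom(spec)
    for va, vb in ((a.ct, b.ct), (a.pet, b.pet), (a.dose, b.dose)):
        np.testing.assert_array_equal(va.data, vb.data)
    np.testing.assert_array_equal(a.truth.lung_mask.data, b.truth.lung_mask.data)


def test_grid_too_small_names_minimum_shape():
    with pytest.raises(ValueError, match="minimum shape"):
        synth.PhantomSpec(grid_shape=(20, 20, 20))
    with pytest.raises(ValueError, match=">= 16"):
        synth.PhantomSpec(grid_shape=(8, 64, 64))


def test_null_model_cohort_has_half_symptomatic():
    cfg = synth.CohortConfig(
        n_patients=10_000, seed=4,
        logistic_coefficients={"intercept": 0.0, "suv_95": 0.0, "age": 0.0, "v30": 0.0})
    df = synth.simulate_cohort(cfg)
    se = 0.5 / np.sqrt(len(df))
    assert abs(df["symptomatic"].mean() - 0.5) < 3 * se


def test_cohort_determinism_and_record_invariants():
    cfg = synth.CohortConfig(n_patients=200, seed=9)
    a, b = synth.simulate_cohort(cfg), synth.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    assert a["rp_grade"].between(0, 5).all()
    assert ((a["rp_grade"] >= 2) == (a["symptomatic"] == 1)).all()
    assert (a["time_days"] > 0).all()
    assert a.loc[a["event"] == 1, "time_days"].max() <= cfg.admin_censor_days


def test_logistic_layer_parameter_recovery_is_unbiased():
    """Mean refit coefficient over replicates sits on the generating value."""
    reps, n = 25, 2000
    ests, se0 = [], None
    for r in range(reps):
        cfg = synth.CohortConfig(n_patients=n, seed=100 + r)
        xs = synth.design_columns(synth.simulate_cohort(cfg), cfg)
        fit = rps.fit_logistic(xs, ["x_suv_95", "x_age", "x_v30"])
        ests.append(fit.coef[["x_suv_95", "x_age", "x_v30"]].to_numpy())
        se0 = fit.se[["x_suv_95", "x_age", "x_v30"]].to_numpy() if se0 is None else se0
    bias = np.mean(ests, axis=0) - np.array([0.40, 0.79, 0.09])
    assert np.all(np.abs(bias) < 3.5 * se0 / np.sqrt(reps))


def test_cox_layer_parameter_recovery_is_unbiased():
    reps, n = 20, 1500
    ests, se0 = [], None
    for r in range(reps):
        cfg = synth.CohortConfig(n_patients=n, seed=300 + r)
        xs = synth.design_columns(synth.simulate_cohort(cfg), cfg)
        fit = rps.cox_fit(xs, ["x_suv_95", "x_age", "x_v30"])
        ests.append(fit.coef.to_numpy())
        se0 = fit.se.to_numpy() if se0 is None else se0
    bias = np.mean(ests, axis=0) - np.array([0.18, 0.34, 0.05])
    assert np.all(np.abs(bias) < 3.5 * se0 / np.sqrt(reps))


def test_median_time_to_symptoms_calibration():
    """Upper two SUV95 terciles reach a ~101-day Kaplan-Meier median."""
    df = synth.simulate_cohort(synth.CohortConfig(n_patients=10_000, seed=1))
    sub = df[df["suv_95"] >= 0.99]
    kmf = KaplanMeierFitter().fit(sub["time_days"], sub["event"])
    assert 90 <= kmf.median_survival_time_ <= 112


def test_suv95_terciles_land_on_design_points():
    df = synth.simulate_cohort(synth.CohortConfig(n_patients=30_000, seed=2))
    lo, hi = np.percentile(df["suv_95"], [100 / 3, 200 / 3])
    assert lo == pytest.approx(0.99, abs=0.01)
    assert hi == pytest.approx(1.20, abs=0.01)


def test_nonfinite_linear_predictor_raises():
    cfg = synth.CohortConfig(
        n_patients=50, seed=0,
        logistic_coefficients={"intercept": float("inf"), "suv_95": 0.4,
                               "age": 0.79, "v30": 0.09})
    with pytest.raises(ValueError, match="non-finite"):
        synth.simulate_cohort(cfg)


def test_reader_sim_zero_error_and_design_shape():
    spec = synth.ReaderSimSpec(n_subjects=10, n_readers=3, inter_reader_sd_pct=0.0,
                               seed=5)
    readings = synth.simulate_reader_readings(spec)
    assert readings.shape == (10, 3)
    assert (readings.nunique(axis=1) == 1).all()


def test_reader_sim_closed_form_limits_of_agreement():
    readings = synth.simulate_reader_readings(synth.ReaderSimSpec(
        n_subjects=200, n_readers=3, inter_reader_sd_pct=3.0, seed=8))
    loa = rps.bland_altman_loa(readings)
    assert loa.loa_halfwidth_pct == pytest.approx(1.96 * 3.0, abs=0.5)
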