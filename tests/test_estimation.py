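"""Sequential fitting, confidence intervals, envelopes and Wald contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mccpk import (
    DepositionState,
    ModelParameters,
    ScanSimConfig,
    compare_parameters,
    fit_absorption,
    fit_mcc,
    normalize_counts,
    parameter_ci,
    retention_curve,
    simulate_scan_dataset,
    trajectory_envelope,
)
from mccpk.estimation import (
    FitResult,
    NormalizationError,
    PairingError,
    UnidentifiabilityError,
)


def make_counts(sid, probe, counts_whole, counts_central, group="G"):
    n = len(counts_whole)
    return pd.DataFrame(
        {
            "subject_id": sid, "group": group, "probe": probe,
            "frame": np.arange(n), "time_min": np.arange(n, dtype=float),
            "counts_whole_lung": counts_whole, "counts_central": counts_central,
        }
    )


def manual_fit_result(estimates, se, stage="mcc", n_points=100, frozen=None):
    names = tuple(estimates)
    tq = stats.t.ppf(0.975, df=n_points - len(names))
    return FitResult(
        stage=stage, param_names=names, estimates=dict(estimates),
        se=dict(se),
        ci_lower={k: estimates[k] - tq * se[k] for k in names},
        ci_upper={k: estimates[k] + tq * se[k] for k in names},
        level=0.95, residual_sum_squares=1.0, n_points=n_points,
        n_params=len(names), covariance=np.diag([se[k] ** 2 for k in names]),
        jacobian=np.zeros((n_points, len(names))), frozen=frozen or {},
    )


class TestNormalizeCounts:
    def test_constant_counts_give_unit_retention(self):
        whole = np.full(20, 5000.0)
        df = pd.concat(
            [make_counts("s1", "TCSC", whole, whole / 2),
             make_counts("s1", "DTPA", whole, whole / 2)]
        )
        (s,) = normalize_counts(df)
        np.testing.assert_allclose(s.retention["TCSC"].values, 1.0)
        np.testing.assert_allclose(s.absorption.values, 0.0)

    def test_halved_counts_give_half_retention(self):
        whole = np.full(41, 8000.0)
        whole[40:] = 4000.0
        df = pd.concat(
            [make_counts("s1", "TCSC", whole, whole / 2),
             make_counts("s1", "DTPA", whole, whole / 2)]
        )
        (s,) = normalize_counts(df)
        assert s.retention["TCSC"].values[40] == pytest.approx(0.5)

    def test_decay_correction_restores_flat_retention(self):
        # counts that decline purely by physical decay of Tc-99m
        t = np.arange(30, dtype=float)
        lam = np.log(2.0) / (6.01 * 60.0)
        whole = 9000.0 * np.exp(-lam * t)
        df = pd.concat(
            [make_counts("s1", "TCSC", whole, whole / 3),
             make_counts("s1", "DTPA", np.full(30, 9000.0), np.full(30, 3000.0))]
        )
        (s,) = normalize_counts(df, decay_correct=True)
        np.testing.assert_allclose(s.retention["TCSC"].values, 1.0, rtol=1e-12)

    def test_zero_frame0_and_missing_probe_errors(self):
        whole = np.full(10, 100.0)
        df = make_counts("s1", "TCSC", whole, whole / 2)
        with pytest.raises(PairingError, match="DTPA"):
            normalize_counts(df)
        whole0 = whole.copy()
        whole0[0] = 0.0
        df = pd.concat(
            [make_counts("s1", "TCSC", whole0, whole0 / 2),
             make_counts("s1", "DTPA", whole, whole / 2)]
        )
        with pytest.raises(NormalizationError):
            normalize_counts(df)

    def test_simulated_group_mean_tracks_model_within_3_sem(self):
        cfg = ScanSimConfig.for_group("NCF", inter_subject_cv=0.0, n_subjects=12, seed=42)
        ds, _ = simulate_scan_dataset(cfg)
        subs = normalize_counts(ds)
        tc = np.array([s.retention["TCSC"].values for s in subs])
        model = retention_curve(
            cfg.params.as_particle(), DepositionState(cfg.c0_mean, cfg.p0_mean),
            subs[0].times,
        ).values
        mean = tc.mean(axis=0)
        sem = tc.std(axis=0, ddof=1) / np.sqrt(len(subs))
        z = np.abs(mean - model)[1:] / sem[1:]  # frame 0 is exact by construction
        assert z.max() < 3.0


class TestSequentialFit:
    def test_noise_free_parameter_recovery(self):
        truth = ModelParameters(k_lt=0.04, ffca=0.7, k_lb=0.002, k_db=0.01)
        cfg = ScanSimConfig(params=truth, n_subjects=3, noise="none",
                            inter_subject_cv=0.0, seed=0)
        ds, _ = simulate_scan_dataset(cfg)
        subs = normalize_counts(ds)
        mcc = fit_mcc(subs, multistart=1)
        ab = fit_absorption(subs, mcc, multistart=1)
        assert mcc.estimates["k_lt"] == pytest.approx(0.04, abs=1e-4)
        assert mcc.estimates["ffca"] == pytest.approx(0.7, abs=1e-4)
        assert ab.estimates["k_lb"] == pytest.approx(0.002, abs=1e-4)
        assert ab.estimates["k_db"] == pytest.approx(0.01, abs=1e-4)

    def test_noise_free_absorption_stage_recovery_at_table_values(self):
        truth = ModelParameters(k_lt=0.035, ffca=0.5, k_lb=0.002, k_db=0.01)
        cfg = ScanSimConfig(params=truth, n_subjects=2, noise="none",
                            inter_subject_cv=0.0, seed=1)
        ds, _ = simulate_scan_dataset(cfg)
        subs = normalize_counts(ds)
        # freeze the MCC stage at the exact truth
        mcc = manual_fit_result({"k_lt": 0.035, "ffca": 0.5},
                                {"k_lt": 0.0, "ffca": 0.0}, n_points=160)
        ab = fit_absorption(subs, mcc, multistart=1)
        assert ab.estimates["k_lb"] == pytest.approx(0.002, abs=1e-4)
        assert ab.estimates["k_db"] == pytest.approx(0.01, abs=1e-4)

    def test_fit_invariant_to_count_rescaling(self, ncf_dataset):
        ds, _ = ncf_dataset
        mcc1 = fit_mcc(normalize_counts(ds), multistart=1)
        scaled = ds.copy()
        scaled["counts_whole_lung"] *= 37.0
        scaled["counts_central"] *= 37.0
        mcc2 = fit_mcc(normalize_counts(scaled), multistart=1)
        assert mcc1.estimates["k_lt"] == pytest.approx(mcc2.estimates["k_lt"], rel=1e-9)
        assert mcc1.estimates["ffca"] == pytest.approx(mcc2.estimates["ffca"], rel=1e-9)

    def test_flat_series_pushes_mcc_product_to_zero(self):
        whole = np.full(80, 6000.0)
        df = pd.concat(
            [make_counts("s1", "TCSC", whole, whole / 2),
             make_counts("s1", "DTPA", whole, whole / 2),
             make_counts("s2", "TCSC", whole, whole / 2),
             make_counts("s2", "DTPA", whole, whole / 2)]
        )
        mcc = fit_mcc(normalize_counts(df), multistart=1)
        # the identifiable quantity is the clearance product, driven to ~0
        assert mcc.estimates["k_lt"] * mcc.estimates["ffca"] < 1e-7
        # fitted curve is flat: no discernible MCC over the 80-min study
        decay = mcc.estimates["ffca"] * (1 - np.exp(-mcc.estimates["k_lt"] * 79.0))
        assert decay < 1e-5

    def test_multistart_matches_single_start_on_well_posed_data(self, ncf_subjects):
        m1 = fit_mcc(ncf_subjects, multistart=1)
        m5 = fit_mcc(ncf_subjects, multistart=5, random_state=0)
        assert m5.estimates["k_lt"] == pytest.approx(m1.estimates["k_lt"], rel=1e-6)


class TestParameterCI:
    def test_matches_closed_form_linear_regression(self):
        # y = theta * t + eps: the nonlinear machinery must reproduce the
        # textbook linear-regression CI exactly
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 10.0, 40)
        y = 2.5 * t + rng.normal(0.0, 1.0, t.size)

        res = optimize.least_squares(lambda th: th[0] * t - y, x0=[1.0])
        fit = FitResult(
            stage="mcc", param_names=("theta",), estimates={"theta": res.x[0]},
            se={"theta": np.nan}, ci_lower={"theta": np.nan},
            ci_upper={"theta": np.nan}, level=0.95,
            residual_sum_squares=float(2 * res.cost), n_points=t.size, n_params=1,
            covariance=np.eye(1), jacobian=res.jac, frozen={},
        )
        fit = parameter_ci(fit)

        theta_hat = np.sum(t * y) / np.sum(t * t)
        s2 = np.sum((y - theta_hat * t) ** 2) / (t.size - 1)
        se = np.sqrt(s2 / np.sum(t * t))
        hw = stats.t.ppf(0.975, df=t.size - 1) * se
        assert fit.estimates["theta"] == pytest.approx(theta_hat, rel=1e-8)
        assert fit.se["theta"] == pytest.approx(se, rel=1e-6)
        assert fit.half_width("theta") == pytest.approx(hw, rel=1e-6)

    def test_duplicating_data_shrinks_ci_by_sqrt2(self, ncf_dataset):
        ds, _ = ncf_dataset
        doubled = pd.concat(
            [ds, ds.assign(subject_id=ds["subject_id"] + "_dup")], ignore_index=True
        )
        m1 = fit_mcc(normalize_counts(ds), multistart=1)
        m2 = fit_mcc(normalize_counts(doubled), multistart=1)
        ratio = m1.half_width("k_lt") / m2.half_width("k_lt")
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_singular_jacobian_raises(self):
        fit = FitResult(
            stage="mcc", param_names=("a", "b"), estimates={"a": 1.0, "b": 1.0},
            se={"a": np.nan, "b": np.nan}, ci_lower={"a": np.nan, "b": np.nan},
            ci_upper={"a": np.nan, "b": np.nan}, level=0.95,
            residual_sum_squares=1.0, n_points=10, n_params=2,
            covariance=np.eye(2), jacobian=np.ones((10, 2)), frozen={},
        )
        with pytest.raises(UnidentifiabilityError):
            parameter_ci(fit)


class TestTrajectoryEnvelope:
    def test_zero_width_cis_collapse_envelope(self):
        fit = manual_fit_result({"k_lt": 0.04, "ffca": 0.6},
                                {"k_lt": 0.0, "ffca": 0.0})
        dep = DepositionState(c0=5e4, p0=5e4)
        env = trajectory_envelope(fit, None, dep, np.arange(0.0, 80.0))
        np.testing.assert_array_equal(env.lower, env.nominal)
        np.testing.assert_array_equal(env.upper, env.nominal)

    def test_single_parameter_monotone_curve_hits_ci_ends(self):
        fit = manual_fit_result({"k_lt": 0.04}, {"k_lt": 0.004},
                                frozen={"ffca": 1.0})
        dep = DepositionState(c0=5e4, p0=1e-6)
        t = np.arange(0.0, 80.0)
        env = trajectory_envelope(fit, None, dep, t)
        lo, hi = fit.ci_lower["k_lt"], fit.ci_upper["k_lt"]
        np.testing.assert_allclose(env.lower, np.exp(-hi * t), rtol=1e-9)
        np.testing.assert_allclose(env.upper, np.exp(-lo * t), rtol=1e-9)
        np.testing.assert_allclose(env.nominal, np.exp(-0.04 * t), rtol=1e-9)

    def test_nominal_equals_point_estimate_curve(self, ncf_subjects):
        mcc = fit_mcc(ncf_subjects, multistart=1)
        ab = fit_absorption(ncf_subjects, mcc, multistart=1)
        dep = DepositionState(c0=5e4, p0=5e4)
        t = np.arange(0.0, 80.0)
        env = trajectory_envelope(mcc, ab, dep, t, target="absorption")
        p_tc = ModelParameters(k_lt=mcc.estimates["k_lt"], ffca=mcc.estimates["ffca"])
        p_dt = ModelParameters(
            k_lt=mcc.estimates["k_lt"], ffca=mcc.estimates["ffca"],
            k_lb=ab.estimates["k_lb"], k_db=ab.estimates["k_db"],
        )
        expected = (
            retention_curve(p_tc, dep, t).values - retention_curve(p_dt, dep, t).values
        )
        np.testing.assert_array_equal(env.nominal, expected)
        assert np.all(env.lower <= env.nominal + 1e-15)
        assert np.all(env.nominal <= env.upper + 1e-15)

    def test_infinite_ci_is_rejected(self):
        fit = manual_fit_result({"k_lt": 0.04, "ffca": 0.6},
                                {"k_lt": 0.004, "ffca": 0.05})
        fit = fit.__class__(**{**fit.__dict__, "ci_upper": {"k_lt": np.inf, "ffca": 0.7}})
        with pytest.raises(ValueError, match="envelope undefined|not finite"):
            trajectory_envelope(fit, None, DepositionState(1e4, 1e4), np.arange(0.0, 10.0))


class TestCompareParameters:
    def test_identical_fits(self):
        f = manual_fit_result({"k_lt": 0.04}, {"k_lt": 0.002})
        z, p = compare_parameters(f, f, "k_lt")
        assert z == 0.0
        assert p == 1.0

    def test_known_normal_quantile(self):
        se = 0.003
        a = manual_fit_result({"k_db": 0.0181 }, {"k_db": se})
        b = manual_fit_result({"k_db": 0.0181 - 1.96 * np.sqrt(2) * se}, {"k_db": se})
        z, p = compare_parameters(a, b, "k_db")
        assert z == pytest.approx(1.96, rel=1e-9)
        assert p == pytest.approx(0.05, rel=0.01)

    def test_table_scale_group_contrast_is_significant(self):
        # CF-IS vs NCF distal absorption at the reported estimate/CI scale
        ncf = manual_fit_result({"k_db": 0.0071}, {"k_db": 0.0005 / 1.96})
        cfis = manual_fit_result({"k_db": 0.0181}, {"k_db": 0.0012 / 1.96})
        z, p = compare_parameters(cfis, ncf, "k_db")
        assert p < 1e-3
        with pytest.raises(KeyError):
            compare_parameters(ncf, cfis, "k_lt")
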