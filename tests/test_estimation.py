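"""FOCE-type objective, fitting, and stepwise covariate selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from tigepk.cohort import CohortConfig, generate_dataset
from tigepk.covariates import CovariateEffect, VarianceModel
from tigepk.estimation import (
    ModelSpec,
    backward_elimination,
    correlation_screen,
    final_model_spec,
    fit,
    forward_inclusion,
    neg2ll_subject,
    ofv,
)
from tigepk.structural import DoseEvent, PKParameters, concentration, concentration_1cpt

LN2PI = math.log(2 * math.pi)


def one_subject_df(obs_times, dvs, dose_amt=100.0, sid=1):
    rows = [
        {"ID": sid, "TIME": 0.0, "EVID": 1, "AMT": dose_amt, "RATE": dose_amt / 0.5,
         "DV": 0.0, "MDV": 1}
    ]
    for t, y in zip(obs_times, dvs):
        rows.append({"ID": sid, "TIME": t, "EVID": 0, "AMT": 0.0, "RATE": 0.0,
                     "DV": y, "MDV": 0})
    return pd.DataFrame(rows)


def plain_spec(omega, sigma=100.0, **kw):
    return ModelSpec(
        n_compartments=2,
        covariate_effects=[],
        variance=VarianceModel(omega=omega, sigma=sigma, **kw),
        fixed_initials={"CL": 6.37, "V1": 32.1, "Q": 39.7, "V2": 113.0},
    )


class TestNeg2llSubject:
    def test_zero_residual_identity_prior(self, final_params):
        # y = f exactly, sigma = 1, one observation, eta = 0, Omega = I(2)
        f = concentration(1.0, [DoseEvent(0.0, 100.0)], final_params)
        df = one_subject_df([1.0], [f])
        spec = plain_spec(omega={"CL": 100.0, "V1": 100.0}, sigma=100.0)
        val = neg2ll_subject(df, spec)
        assert val == pytest.approx(LN2PI + math.log(f**2) + 2 * LN2PI, rel=1e-10)

    def test_proportional_error_scale_invariance(self, final_params):
        # scaling dose and DV jointly leaves the residual quadratic unchanged;
        # only the ln(sigma^2 f^2) terms shift, by 2 ln c per observation
        times = [1.0, 6.0]
        f = concentration(np.array(times), [DoseEvent(0.0, 100.0)], final_params)
        y = f * 1.07  # a fixed 7% residual on both points
        g1 = neg2ll_subject(one_subject_df(times, y), plain_spec({}, sigma=10.0))
        g2 = neg2ll_subject(
            one_subject_df(times, 3.0 * y, dose_amt=300.0), plain_spec({}, sigma=10.0)
        )
        assert g2 - g1 == pytest.approx(2 * 2 * math.log(3.0), rel=1e-9)

    def test_matches_hand_computed_formula(self, final_params):
        times = [1.0, 6.0]
        y = [1.9, 0.8]
        eta = {"CL": 0.2, "V1": -0.1}
        omega = {"CL": 27.0, "V1": 72.5}
        sigma = 2.02
        spec = plain_spec(omega=omega, sigma=sigma)
        val = neg2ll_subject(one_subject_df(times, y), spec, eta=eta)
        # independent evaluation of the conditional -2 log-likelihood
        p = PKParameters(
            CL=6.37 * math.exp(0.2), V1=32.1 * math.exp(-0.1), Q=39.7, V2=113.0
        )
        f = concentration(np.array(times), [DoseEvent(0.0, 100.0)], p)
        s = sigma / 100.0
        expected = sum(
            LN2PI + math.log(s**2 * fi**2) + (yi - fi) ** 2 / (s**2 * fi**2)
            for fi, yi in zip(f, y)
        )
        o = np.array([27.0, 72.5]) / 100.0
        expected += (
            (0.2 / o[0]) ** 2 + (-0.1 / o[1]) ** 2
            + 2 * LN2PI + math.log(o[0] ** 2 * o[1] ** 2)
        )
        assert val == pytest.approx(expected, rel=1e-9)


class TestOFV:
    def test_zero_omega_limit_is_fixed_effects_loglik(self, final_params):
        times = [1.0, 6.0, 12.0]
        f = concentration(np.array(times), [DoseEvent(0.0, 100.0)], final_params)
        y = f * np.array([1.02, 0.97, 1.01])
        df = one_subject_df(times, y)
        spec = plain_spec(omega={}, sigma=2.02)
        s = 0.0202
        expected = sum(
            LN2PI + math.log(s**2 * fi**2) + (yi - fi) ** 2 / (s**2 * fi**2)
            for fi, yi in zip(f, y)
        )
        assert ofv(df, spec) == pytest.approx(expected, rel=1e-9)

    def test_additive_over_subjects(self):
        df, _ = generate_dataset(CohortConfig(n_subjects=4, seed=21))
        spec = final_model_spec()
        base = ofv(df, spec)
        shifted = df.copy()
        shifted["ID"] = shifted["ID"] + 100
        doubled = pd.concat([df, shifted], ignore_index=True)
        assert ofv(doubled, spec) == pytest.approx(2 * base, rel=1e-8)

    def test_invariant_to_subject_order(self):
        df, _ = generate_dataset(CohortConfig(n_subjects=5, seed=22))
        spec = final_model_spec()
        base = ofv(df, spec)
        order = [3, 1, 5, 2, 4]
        permuted = pd.concat(
            [df[df["ID"] == i] for i in order], ignore_index=True
        )
        assert ofv(permuted, spec) == pytest.approx(base, rel=1e-9)

    def test_matches_adaptive_quadrature_oracle(self):
        # 3 subjects, one-compartment, additive error, IIV on CL only:
        # brute-force marginalization over eta vs the Laplace/FOCE value
        rng = np.random.default_rng(5)
        cl_typ, v1 = 5.0, 30.0
        om, sig_add = 0.3, 0.5
        times = np.array([1.0, 3.0, 6.0, 10.0])
        doses = [DoseEvent(0.0, 100.0)]
        frames = []
        for sid in range(1, 4):
            eta = rng.standard_normal() * om
            f = concentration_1cpt(times, doses, cl_typ * math.exp(eta), v1)
            y = f + rng.standard_normal(len(times)) * sig_add
            frames.append(one_subject_df(times, y, sid=sid))
        df = pd.concat(frames, ignore_index=True)
        spec = ModelSpec(
            n_compartments=1,
            covariate_effects=[],
            variance=VarianceModel(
                omega={"CL": 100 * om}, sigma=0.0, sigma_add=sig_add,
                residual_form="additive",
            ),
            fixed_initials={"CL": cl_typ, "V1": v1},
        )
        oracle = 0.0
        for sid in range(1, 4):
            g = df[df["ID"] == sid]
            y = g.loc[g["EVID"] == 0, "DV"].to_numpy()

            def integrand(eta):
                f = concentration_1cpt(times, doses, cl_typ * math.exp(eta), v1)
                lik = np.prod(
                    np.exp(-0.5 * ((y - f) / sig_add) ** 2)
                    / (sig_add * math.sqrt(2 * math.pi))
                )
                prior = math.exp(-0.5 * (eta / om) ** 2) / (om * math.sqrt(2 * math.pi))
                return lik * prior

            L, _ = integrate.quad(integrand, -8 * om, 8 * om, limit=200)
            oracle += -2.0 * math.log(L)
        assert ofv(df, spec) == pytest.approx(oracle, abs=2.0)


class TestFit:
    def test_recovers_parameters_at_vanishing_noise(self):
        gen = plain_spec(omega={}, sigma=0.1)
        df, _ = generate_dataset(CohortConfig(n_subjects=12, seed=31, model=gen))
        start = ModelSpec(
            n_compartments=2,
            covariate_effects=[],
            variance=VarianceModel(omega={}, sigma=0.2),
            fixed_initials={"CL": 8.0, "V1": 26.0, "Q": 50.0, "V2": 90.0},
        )
        r = fit(df, start, compute_se=False)
        assert r.converged
        for name, true in (("CL", 6.37), ("V1", 32.1), ("Q", 39.7), ("V2", 113.0)):
            assert r.estimates[name] == pytest.approx(true, rel=0.01)

    def test_optimum_stable_under_perturbed_start(self):
        gen = plain_spec(omega={}, sigma=0.1)
        df, _ = generate_dataset(CohortConfig(n_subjects=12, seed=31, model=gen))
        tight = dict(compute_se=False, ftol=1e-12, gtol=1e-8, eps=1e-6)
        r_truth = fit(df, plain_spec(omega={}, sigma=0.1), **tight)
        start = ModelSpec(
            n_compartments=2,
            covariate_effects=[],
            variance=VarianceModel(omega={}, sigma=0.2),
            fixed_initials={"CL": 8.0, "V1": 26.0, "Q": 50.0, "V2": 90.0},
        )
        r_pert = fit(df, start, **tight)
        assert abs(r_truth.ofv - r_pert.ofv) < 0.5

    def test_aic_definition(self, small_fit):
        assert small_fit.aic == pytest.approx(
            small_fit.ofv + 2 * small_fit.n_parameters
        )
        assert small_fit.n_parameters == final_model_spec().n_estimated()

    def test_two_compartment_data_prefers_two_compartments(self):
        gen = plain_spec(omega={"CL": 27.0, "V1": 40.0}, sigma=2.02)
        df, _ = generate_dataset(CohortConfig(n_subjects=12, seed=33, model=gen))
        spec2 = ModelSpec(
            n_compartments=2,
            variance=VarianceModel(omega={"CL": 27.0, "V1": 40.0}, sigma=2.0),
            fixed_initials={"CL": 6.0, "V1": 32.0, "Q": 40.0, "V2": 110.0},
        )
        spec1 = ModelSpec(
            n_compartments=1,
            variance=VarianceModel(omega={"CL": 27.0, "V1": 40.0}, sigma=2.0),
            fixed_initials={"CL": 6.0, "V1": 60.0},
        )
        r2 = fit(df, spec2, compute_se=False)
        r1 = fit(df, spec1, compute_se=False)
        assert r2.aic < r1.aic

    def test_ebes_shape_and_rse_presence(self, small_dataset):
        r = fit(small_dataset, final_model_spec(), compute_se=True, maxiter=30)
        assert list(r.ebes.columns) == ["ID", "eta_CL", "eta_V1", "eta_Q"]
        assert len(r.ebes) == 20
        assert r.rse is not None and all(v >= 0 for v in r.rse.values())


# --- stepwise selection mechanics, exercised with a deterministic stub fitter


class _StubFit:
    def __init__(self, spec, value):
        self.spec = spec
        self.ofv = value
        self.converged = True
        self.message = ""

    def fitted_spec(self):
        return self.spec


def make_stub_fitter(ofv_by_effects, fail_on=()):
    def fitter(dataset, spec, **kwargs):
        key = frozenset(spec.effect_name(e) for e in spec.covariate_effects)
        if key & set(fail_on):
            raise RuntimeError("stub candidate failure")
        return _StubFit(spec, ofv_by_effects[key])

    return fitter


E_BW = CovariateEffect("V1", "WT", "power", 0.1, 61.0)
E_NULL = CovariateEffect("V1", "WBC", "power", 0.1, 8.3)


class TestForwardInclusion:
    def test_threshold_boundary_inclusive(self):
        fitter = make_stub_fitter({
            frozenset(): 100.0,
            frozenset({"WT_V1"}): 100.0 - 3.84,      # exactly at the cutoff
            frozenset({"WBC_V1"}): 100.0 - 3.83,
            frozenset({"WT_V1", "WBC_V1"}): 100.0 - 3.84 - 1.0,
        })
        spec, log = forward_inclusion(None, plain_spec({}), [E_BW, E_NULL], fitter=fitter)
        names = [spec.effect_name(e) for e in spec.covariate_effects]
        assert names == ["WT_V1"]

    def test_no_qualifying_candidate_returns_base(self):
        fitter = make_stub_fitter({
            frozenset(): 100.0,
            frozenset({"WT_V1"}): 98.0,
            frozenset({"WBC_V1"}): 99.0,
        })
        spec, log = forward_inclusion(None, plain_spec({}), [E_BW, E_NULL], fitter=fitter)
        assert spec.covariate_effects == []
        assert all(entry["included"] is False for entry in log)

    def test_largest_drop_wins_and_log_records_all(self):
        fitter = make_stub_fitter({
            frozenset(): 100.0,
            frozenset({"WT_V1"}): 80.0,
            frozenset({"WBC_V1"}): 90.0,
            frozenset({"WT_V1", "WBC_V1"}): 79.0,
        })
        spec, log = forward_inclusion(None, plain_spec({}), [E_BW, E_NULL], fitter=fitter)
        names = [spec.effect_name(e) for e in spec.covariate_effects]
        assert names == ["WT_V1"]
        tested = {(e["step"], e["candidate"]) for e in log}
        assert tested == {(1, "WT_V1"), (1, "WBC_V1"), (2, "WBC_V1")}

    def test_candidate_failure_is_skipped_not_fatal(self):
        fitter = make_stub_fitter(
            {
                frozenset(): 100.0,
                frozenset({"WBC_V1"}): 90.0,
                frozenset({"WT_V1", "WBC_V1"}): 89.5,
            },
            fail_on={"WT_V1"},
        )
        spec, log = forward_inclusion(None, plain_spec({}), [E_BW, E_NULL], fitter=fitter)
        names = [spec.effect_name(e) for e in spec.covariate_effects]
        assert names == ["WBC_V1"]
        assert any(e["error"] is not None for e in log)


class TestBackwardElimination:
    def test_threshold_boundary_removes_at_exact_value(self):
        full = plain_spec({}).with_effect(E_BW)
        fitter = make_stub_fitter({
            frozenset({"WT_V1"}): 100.0,
            frozenset(): 100.0 + 10.83,  # removal cost exactly 10.83 -> removed
        })
        spec, log = backward_elimination(None, full, fitter=fitter)
        assert spec.covariate_effects == []

    def test_costly_effects_retained(self):
        full = plain_spec({}).with_effect(E_BW)
        fitter = make_stub_fitter({
            frozenset({"WT_V1"}): 100.0,
            frozenset(): 100.0 + 10.84,  # strictly above: retained
        })
        spec, log = backward_elimination(None, full, fitter=fitter)
        assert [spec.effect_name(e) for e in spec.covariate_effects] == ["WT_V1"]


class TestCorrelationScreen:
    def test_flags_correlated_pairs_only(self):
        rng = np.random.default_rng(2)
        n = 60
        wt = rng.uniform(40, 100, n)
        df = pd.DataFrame({
            "ID": np.arange(n), "EVID": 0, "TIME": 0.0,
            "WT": wt,
            "BMI": wt * 0.35 + rng.normal(0, 0.5, n),  # strongly tied to WT
            "WBC": rng.uniform(2, 20, n),
        })
        flagged = correlation_screen(df, ["WT", "BMI", "WBC"], cutoff=0.5)
        pairs = {(a, b) for a, b, _ in flagged}
        assert ("WT", "BMI") in pairs
        assert all("WBC" not in p for p in pairs)


class TestModelSpec:
    def test_duplicate_effect_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            plain_spec({}).with_effect(E_BW).with_effect(
                CovariateEffect("V1", "WT", "linear", 0.5, 61.0)
            )

    def test_effect_on_absent_compartment_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(
                n_compartments=1,
                covariate_effects=[CovariateEffect("Q", "WT", "power", 1.0, 61.0)],
                variance=VarianceModel(omega={"CL": 30.0}),
                fixed_initials={"CL": 6.0, "V1": 30.0},
            )
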