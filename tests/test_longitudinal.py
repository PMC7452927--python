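"""Longitudinal models: structural functions, Laplace fits, covariate search."""

import numpy as np
import pandas as pd
import pytest

import ipssirt as ip
from ipssirt import reference as ref
from ipssirt.longitudinal import (
    CovariateEffect,
    JointIRTModel,
    LatentDisabilityModel,
    LongitudinalParams,
    RandomEffectsSpec,
    TotalScoreModel,
    covariate_search,
)
from ipssirt.simulate import TrialDesign, default_truth, simulate_trial


class TestStructural:
    def test_placebo_zero_at_baseline(self):
        assert ip.placebo_response(0.0, -4.0, 3.0) == 0.0

    def test_half_life_definition(self):
        assert ip.placebo_response(3.0, -4.0, 3.0) == pytest.approx(-2.0)

    def test_weibull_value_at_half_life(self):
        # exponent 1.53: 1 - exp(-(ln 2)^1.53) ~ 0.435
        val = ip.placebo_response(3.0, 1.0, 3.0, wei=1.53)
        assert val == pytest.approx(1 - np.exp(-np.log(2) ** 1.53), rel=1e-12)
        assert val == pytest.approx(0.435, abs=0.001)

    def test_weibull_one_reduces_to_exponential(self):
        t = np.linspace(0, 6, 25)
        np.testing.assert_allclose(
            ip.placebo_response(t, -2.0, 2.5, wei=1.0),
            ip.placebo_response(t, -2.0, 2.5),
        )

    def test_tprog_must_be_positive(self):
        with pytest.raises(ValueError, match="tprog"):
            ip.placebo_response(1.0, -4.0, 0.0)

    def test_total_score_asymptotes(self):
        params, _, _ = ref.ipss_longitudinal_params()
        # placebo arm: baseline + pmax; active: adds the drug offset
        assert ip.structural_prediction(params, "placebo", 1e9) == pytest.approx(
            19.6 - 4.12, abs=1e-6
        )
        assert ip.structural_prediction(params, "20 mg", 1e9) == pytest.approx(
            19.6 - 4.12 - 1.98, abs=1e-6
        )
        assert ip.structural_prediction(params, "placebo", 0.0) == pytest.approx(19.6)
        with pytest.raises(ValueError, match="negative"):
            ip.structural_prediction(params, "placebo", -1.0)

    def test_boxcox_eta(self):
        assert ip.boxcox_eta(0.5, 1e-12) == pytest.approx(0.5)
        assert ip.boxcox_eta(0.0, 1.87) == 0.0
        assert ip.boxcox_eta(1.0, 1.87) == pytest.approx(
            (np.exp(1.87) - 1) / 1.87, rel=1e-12
        )
        assert ip.boxcox_eta(1.0, 1.87) == pytest.approx(2.935, abs=0.001)


class TestRandomEffectsSpec:
    def test_psd_validation(self):
        with pytest.raises(ValueError, match="PSD"):
            RandomEffectsSpec(
                distributions={"a": "normal", "b": "normal", "c": "normal"},
                sd={"a": 1.0, "b": 1.0, "c": 1.0},
                correlations={("a", "b"): 0.95, ("b", "c"): 0.95, ("a", "c"): -0.95},
            ).covariance()

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            RandomEffectsSpec(distributions={"a": "cauchy"}, sd={"a": 1.0})


@pytest.fixture(scope="module")
def small_total_trial():
    params, iiv, _ = ref.ipss_longitudinal_params()
    design = TrialDesign(n_patients=150, seed=31,
                         visit_times=(0.0, 0.5, 1.0, 3.0, 6.0))
    data = ip.simulate_total_score_trial(design, params, iiv, seed=31)
    return data, iiv


class TestTotalScoreModel:
    def test_loose_recovery_and_drug_nesting(self, small_total_trial):
        data, iiv = small_total_trial
        full = TotalScoreModel(data, iiv=iiv).fit(maxiter=200, ftol=1e-8)
        red = TotalScoreModel(data, iiv=iiv, include_drug=False).fit(
            maxiter=200, ftol=1e-8
        )
        assert full.converged and red.converged
        assert full.params["baseline"] == pytest.approx(19.6, abs=1.0)
        assert full.params["drug"] == pytest.approx(-1.98, abs=1.5)
        # nesting: the full model can only fit better
        assert full.ofv <= red.ofv + 1e-6
        assert red.k_params == full.k_params - 1

    def test_null_drug_recovered_near_zero(self):
        params, iiv, _ = ref.ipss_longitudinal_params()
        from dataclasses import replace

        null = replace(params, drug=0.0)
        design = TrialDesign(n_patients=150, seed=77,
                             visit_times=(0.0, 1.0, 3.0, 6.0))
        data = ip.simulate_total_score_trial(design, null, iiv, seed=77)
        res = TotalScoreModel(data, iiv=iiv).fit(maxiter=200, ftol=1e-8)
        assert res.params["drug"] == pytest.approx(0.0, abs=0.8)

    def test_summary_and_se(self, small_total_trial):
        data, iiv = small_total_trial
        res = TotalScoreModel(data, iiv=iiv).fit(maxiter=120, ftol=1e-7,
                                                 compute_se=True)
        txt = res.summary()
        assert "OFV" in txt and "baseline" in txt
        assert res.se_table["drug"] > 0


class TestLatentDisabilityModel:
    @pytest.fixture(scope="class")
    def ebe_fixture(self, uni_bank, uni_shift):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(n_patients=150, seed=41,
                             visit_times=(0.0, 0.5, 1.0, 3.0, 6.0))
        data = simulate_trial(design, truth)
        pseudo = ip.reshape_idvis(data)
        ebe = ip.estimate_disability(uni_bank, uni_shift, pseudo)
        meta = data[["patient_id", "time_months", "dose_mg"]]
        return ebe.merge(meta, on=["patient_id", "time_months"]), truth

    def test_missing_se_rejected(self, ebe_fixture):
        ebt, truth = ebe_fixture
        broken = ebt.copy()
        broken.loc[broken.index[0], "se"] = np.nan
        with pytest.raises(ValueError, match="standard error"):
            LatentDisabilityModel(broken, iiv=truth.iiv)

    def test_drug_recovery_and_se_zero_limit(self, ebe_fixture):
        ebt, truth = ebe_fixture
        res = LatentDisabilityModel(ebt, iiv=truth.iiv).fit(maxiter=200, ftol=1e-8)
        assert res.converged
        assert res.params["drug"] == pytest.approx(-0.542, abs=0.4)
        # with the SEs forced to ~0 the model reduces to a plain additive fit:
        # the estimated additive term must then absorb the EBE noise
        tiny = ebt.copy()
        tiny["se"] = 1e-8
        res2 = LatentDisabilityModel(tiny, iiv=truth.iiv).fit(maxiter=150, ftol=1e-7)
        assert res2.params["sigma_add"] > res.params["sigma_add"]


class TestJointModel:
    @pytest.fixture(scope="class")
    def joint_trial(self):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(n_patients=80, seed=51,
                             visit_times=(0.0, 1.0, 3.0, 6.0))
        return simulate_trial(design, truth), truth

    @pytest.fixture(scope="class")
    def joint_full_fit(self, joint_trial):
        data, truth = joint_trial
        return JointIRTModel(data, truth.item_bank, iiv=truth.iiv).fit(
            maxiter=150, ftol=1e-7
        )

    def test_patient_permutation_leaves_ofv_unchanged(self, joint_trial):
        data, truth = joint_trial
        m = JointIRTModel(data, truth.item_bank, iiv=truth.iiv)
        v1 = m.ofv()
        perm = data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        perm = perm.sort_values(["patient_id", "time_months"], ascending=[False, True])
        m2 = JointIRTModel(perm.reset_index(drop=True), truth.item_bank, iiv=truth.iiv)
        assert m2.ofv() == pytest.approx(v1, abs=1e-5)

    def test_fixed_icc_fit_recovers_drug_and_nests(self, joint_trial, joint_full_fit):
        data, truth = joint_trial
        full = joint_full_fit
        red = JointIRTModel(data, truth.item_bank, iiv=truth.iiv,
                            include_drug=False).fit(maxiter=150, ftol=1e-7)
        assert full.ofv <= red.ofv + 1e-6
        assert full.params["drug"] == pytest.approx(-0.542, abs=0.6)

    def test_sequential_psi_ippse_agrees_with_joint_fit(self, joint_trial,
                                                        joint_full_fit, uni_shift):
        # the rationale for the sequential shortcut: modelling the MAP
        # disabilities with their SEs reproduces the joint item-level
        # drug-effect estimate to well within one standard error
        data, truth = joint_trial
        pseudo = ip.reshape_idvis(data)
        ebe = ip.estimate_disability(truth.item_bank, uni_shift, pseudo)
        ebt = ebe.merge(data[["patient_id", "time_months", "dose_mg"]],
                        on=["patient_id", "time_months"])
        seq = LatentDisabilityModel(ebt, iiv=truth.iiv).fit(maxiter=150, ftol=1e-7)
        assert abs(seq.params["drug"] - joint_full_fit.params["drug"]) < 0.35

    def test_reestimating_icc_changes_ofv_insignificantly(self, joint_trial):
        # on truth-simulated data the fixed ICCs are correct, so freeing all
        # 42 item parameters should gain less than the chi-squared criterion
        data, truth = joint_trial
        fixed = JointIRTModel(data, truth.item_bank, iiv=truth.iiv).fit(
            maxiter=120, ftol=1e-7
        )
        free = JointIRTModel(data, truth.item_bank, iiv=truth.iiv,
                             re_estimate_icc=True).fit(maxiter=60, ftol=1e-6)
        from scipy.stats import chi2

        gain = fixed.ofv - free.ofv
        assert gain < chi2.isf(0.05, 42)


class TestCovariateSearch:
    def test_empty_candidates_return_base(self, uni_bank, uni_shift):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(n_patients=60, seed=61, visit_times=(0.0, 3.0))
        data = simulate_trial(design, truth)
        pseudo = ip.reshape_idvis(data)
        ebe = ip.estimate_disability(uni_bank, uni_shift, pseudo)
        ebt = ebe.merge(data[["patient_id", "time_months", "dose_mg"]],
                        on=["patient_id", "time_months"])

        def fit_fn(covs):
            return LatentDisabilityModel(ebt, iiv=truth.iiv, covariates=covs).fit(
                maxiter=80, ftol=1e-7
            )

        res, selected, trace = covariate_search(fit_fn, [])
        assert selected == [] and trace.empty

    def test_strong_covariate_selected_noise_dropped(self, uni_bank, uni_shift):
        truth = default_truth("uni")  # includes QoL 0.325 on baseline
        design = TrialDesign(n_patients=200, seed=63, visit_times=(0.0, 1.0, 3.0, 6.0))
        data = simulate_trial(design, truth)
        pseudo = ip.reshape_idvis(data)
        ebe = ip.estimate_disability(uni_bank, uni_shift, pseudo)
        rng = np.random.default_rng(1)
        meta = data[["patient_id", "time_months", "dose_mg", "qol_base"]].copy()
        ebt = ebe.merge(meta, on=["patient_id", "time_months"])
        noise = pd.DataFrame({
            "patient_id": data["patient_id"].unique(),
            "noise_cov": rng.normal(size=data["patient_id"].nunique()),
        })
        ebt = ebt.merge(noise, on="patient_id")

        def fit_fn(covs):
            return LatentDisabilityModel(ebt, iiv=truth.iiv, covariates=covs).fit(
                maxiter=100, ftol=1e-7
            )

        candidates = [
            CovariateEffect("baseline", "qol_base", "additive", 0.0, 4.0),
            CovariateEffect("baseline", "noise_cov", "additive", 0.0, 0.0),
        ]
        res, selected, trace = covariate_search(fit_fn, candidates)
        names = {(c.parameter, c.covariate) for c in selected}
        assert ("baseline", "qol_base") in names
        assert ("baseline", "noise_cov") not in names
        assert set(trace["phase"]) <= {"forward", "backward"}
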