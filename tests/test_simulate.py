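"""Synthetic-trial generator: design validation, reproducibility, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ipssirt as ip
from ipssirt.icc import ITEM_COLS
from ipssirt.simulate import (
    SimulationTruth,
    TrialDesign,
    default_truth,
    generate_item_responses,
    generate_population,
    generate_trajectories,
)


class TestDesignValidation:
    def test_allocation_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrialDesign(arms=(("placebo", 0.0, 0.5), ("10 mg", 10.0, 0.3)))

    def test_visit_times_must_increase_from_zero(self):
        with pytest.raises(ValueError, match="strictly increase"):
            TrialDesign(visit_times=(0.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="start at 0"):
            TrialDesign(visit_times=(1.0, 2.0))

    def test_rates_in_unit_interval(self):
        with pytest.raises(ValueError, match="rates"):
            TrialDesign(item_missingness_rate=1.5)

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            TrialDesign(n_patients=0)

    def test_truth_requires_covariate_distributions(self, uni_bank):
        from ipssirt.longitudinal import CovariateEffect
        from ipssirt.reference import latent_longitudinal_params

        params, iiv, _ = latent_longitudinal_params()
        with pytest.raises(ValueError, match="no distribution"):
            SimulationTruth(
                item_bank=uni_bank,
                longitudinal=params,
                iiv=iiv,
                covariate_effects=(
                    CovariateEffect("baseline", "shoe_size", "additive", 0.1, 42.0),
                ),
            )


class TestPopulation:
    def test_seeded_reproducibility_and_patient_stream_stability(self):
        truth = default_truth("uni")
        d1 = TrialDesign(n_patients=40, seed=5)
        a = generate_population(d1, truth)
        b = generate_population(d1, truth)
        pd.testing.assert_frame_equal(a, b)
        # growing the trial must not reshuffle earlier patients
        d2 = TrialDesign(n_patients=55, seed=5)
        c = generate_population(d2, truth)
        pd.testing.assert_frame_equal(a, c.iloc[: len(a)].reset_index(drop=True))

    def test_arm_counts_within_binomial_bounds(self):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(n_patients=403, seed=2, screening_threshold=None)
        pop = generate_population(design, truth)
        counts = pop["arm"].value_counts()
        lo = stats.binom.ppf(0.005, 403, 0.25)
        hi = stats.binom.ppf(0.995, 403, 0.25)
        assert len(counts) == 4
        for arm, n in counts.items():
            assert lo <= n <= hi, (arm, n)

    def test_screening_rule_binds_at_screening_only(self):
        truth = default_truth("uni")
        design = TrialDesign(n_patients=120, seed=9)
        pop = generate_population(design, truth)
        assert (pop["screening_total"] >= 13).all()
        # ... but the baseline visit may still fall below the cut-off
        data = ip.simulate_trial(design, truth)
        base = data[data["time_months"] == 0]["total"]
        assert base.min() < 13


class TestTrajectories:
    def test_no_iiv_placebo_baseline_at_t0(self, uni_bank):
        from ipssirt.longitudinal import LongitudinalParams, RandomEffectsSpec

        params = LongitudinalParams(baseline=0.3, pmax=-1.0, tprog=3.0, drug=-0.5)
        iiv = RandomEffectsSpec(
            distributions={"baseline": "normal", "pmax": "normal",
                           "tprog": "lognormal", "drift": "normal"},
            sd={"baseline": 0.0, "pmax": 0.0, "tprog": 0.0, "drift": 0.0},
        )
        truth = SimulationTruth(item_bank=uni_bank, longitudinal=params, iiv=iiv)
        design = TrialDesign(n_patients=4, seed=1, screening_threshold=None)
        pop = generate_population(design, truth)
        traj = generate_trajectories(pop, truth, (0.0, 1e7))
        t0 = traj[traj["time_months"] == 0]
        np.testing.assert_allclose(t0["psi"], 0.3, atol=1e-12)
        # exponential asymptote: baseline + pmax (+ drug on active arms)
        tinf = traj[traj["time_months"] > 0]
        expect = 0.3 - 1.0 + np.where(tinf["dose_mg"] > 0, -0.5, 0.0)
        np.testing.assert_allclose(tinf["psi"], expect, atol=1e-6)

    def test_reference_active_asymptote(self):
        # typical latent endpoint: baseline + pmax + drug = 0.0283 - 1.03 - 0.542
        from ipssirt.reference import latent_longitudinal_params

        params, _, _ = latent_longitudinal_params()
        val = ip.structural_prediction(params, "30 mg", 1e8)
        assert val == pytest.approx(0.0283 - 1.03 - 0.542, abs=1e-6)

    def test_negative_times_rejected(self, uni_bank):
        truth = default_truth("uni")
        design = TrialDesign(n_patients=3, seed=1, screening_threshold=None)
        pop = generate_population(design, truth)
        with pytest.raises(ValueError, match="negative"):
            generate_trajectories(pop, truth, (-1.0, 0.0))


class TestItemResponses:
    def test_record_count_and_total_identity(self):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(n_patients=50, seed=3, screening_threshold=None)
        data = ip.simulate_trial(design, truth)
        assert len(data) == 50 * 8
        items = data[ITEM_COLS]
        assert items.notna().sum().sum() == 50 * 8 * 7
        assert items.to_numpy().min() >= 0 and items.to_numpy().max() <= 5
        np.testing.assert_allclose(items.sum(axis=1), data["total"])
        assert data["total"].between(0, 35).all()

    def test_very_low_disability_scores_zero_except_nocturia(self, uni_bank, uni_shift):
        from ipssirt.grm import simulate_item_scores

        rng = np.random.default_rng(0)
        psi = np.full(4000, -10.0)
        zero_frac = {}
        for it in uni_bank.items:
            y = simulate_item_scores(it, psi, rng)
            zero_frac[it.index] = np.mean(y == 0)
        for j in range(1, 7):
            assert zero_frac[j] > 0.97, j
        # nocturia's first threshold is so low that scores >= 1 stay common
        p_nonzero = float(ip.cumulative_probability(uni_bank.items[6], -10.0, 1))
        assert 0.1 < p_nonzero < 0.4
        se = np.sqrt(p_nonzero * (1 - p_nonzero) / 4000)
        assert abs((1 - zero_frac[7]) - p_nonzero) < 4 * se

    def test_missingness_and_dropout(self):
        truth = default_truth("uni", with_covariates=False)
        design = TrialDesign(
            n_patients=60, seed=4, screening_threshold=None,
            item_missingness_rate=0.1, dropout_rate=0.15,
        )
        data = ip.simulate_trial(design, truth)
        assert len(data) < 60 * 8  # dropout removed visits
        frac_missing = data[ITEM_COLS].isna().mean().mean()
        assert 0.05 < frac_missing < 0.15
        # dropout is monotone: observed visit indices are a prefix per patient
        for _, grp in data.groupby("patient_id"):
            idx = np.sort(grp["visit_idx"].to_numpy())
            np.testing.assert_array_equal(idx, np.arange(idx.size))

    def test_dimension_mismatch_rejected(self, bi_bank):
        truth = default_truth("uni")
        design = TrialDesign(n_patients=3, seed=1, screening_threshold=None)
        pop = generate_population(design, truth)
        traj = generate_trajectories(pop, truth, (0.0, 1.0))
        with pytest.raises(ValueError, match="dimension"):
            generate_item_responses(traj, bi_bank, design)


class TestIdvisSimulation:
    def test_baseline_marginal_is_standard_normal(self, uni_bank, uni_shift):
        ds = ip.simulate_idvis_dataset(
            uni_bank, uni_shift, n_patients=4000, visit_times=(0.0,),
            seed=13, return_psi=True,
        )
        stat, p = stats.kstest(ds["psi"], "norm")
        assert p > 0.01

    def test_post_rows_follow_shifted_distribution(self, uni_bank, uni_shift):
        ds = ip.simulate_idvis_dataset(
            uni_bank, uni_shift, n_patients=1500, visit_times=(0.0, 3.0),
            seed=14, return_psi=True,
        )
        post = ds[ds["time_months"] > 0]["psi"]
        stat, p = stats.kstest(
            (post - uni_shift.post_mean[0]) / np.sqrt(uni_shift.post_variance[0]),
            "norm",
        )
        assert p > 0.01
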