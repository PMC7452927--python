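"""Graded-response-model kernels: probabilities, information, likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ipssirt as ip
from ipssirt.grm import (
    ItemBank,
    ItemParameters,
    increments_from_thresholds,
    simulate_item_scores,
    thresholds_from_increments,
)


class TestThresholds:
    def test_cumulative_sum_of_reported_difficulties(self):
        tau = thresholds_from_increments([-4.09, 1.82, 1.68, 1.41, 1.27])
        np.testing.assert_allclose(tau, [-4.09, -2.27, -0.59, 0.82, 2.09], atol=1e-12)

    def test_single_threshold_identity(self):
        np.testing.assert_allclose(thresholds_from_increments([-2.0]), [-2.0])

    def test_nonpositive_increment_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            thresholds_from_increments([0.0, -1.0, 1.0, 1.0, 1.0])

    def test_roundtrip(self):
        raw = np.array([-3.1, 1.72, 1.68, 1.67, 1.67])
        np.testing.assert_allclose(
            increments_from_thresholds(thresholds_from_increments(raw)), raw
        )


class TestProbabilities:
    def test_cumulative_half_at_threshold(self, uni_bank):
        for it in uni_bank.items:
            for k in range(1, 6):
                assert ip.cumulative_probability(it, it.thresholds[k - 1], k) == pytest.approx(0.5)

    def test_cumulative_limits(self, uni_bank):
        it = uni_bank.items[0]
        assert ip.cumulative_probability(it, 60.0, 1) == pytest.approx(1.0)
        assert ip.cumulative_probability(it, -60.0, 5) == pytest.approx(0.0)

    def test_item1_logistic_value(self, uni_bank):
        # a = 1.38, tau1 = -4.09, psi = 0
        expected = 1.0 / (1.0 + np.exp(-1.38 * 4.09))
        assert ip.cumulative_probability(uni_bank.items[0], 0.0, 1) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.9965, abs=1e-4)

    def test_category_probabilities_match_difference_oracle(self, uni_bank):
        # brute-force evaluation of the two defining equations
        it = uni_bank.items[0]
        psi = 0.0
        q = [1.0] + [
            float(ip.cumulative_probability(it, psi, k)) for k in range(1, 6)
        ] + [0.0]
        oracle = np.array([q[k] - q[k + 1] for k in range(6)])
        np.testing.assert_allclose(ip.category_probabilities(it, psi), oracle, atol=1e-14)

    def test_extreme_low_disability_all_zero(self, uni_bank):
        p = ip.category_probabilities(uni_bank.items[0], -40.0)
        np.testing.assert_allclose(p, [1, 0, 0, 0, 0, 0], atol=1e-12)

    @given(psi=st.floats(-12, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one_and_nonnegative(self, psi):
        from ipssirt import reference

        for it in reference.unidimensional_bank().items:
            p = ip.category_probabilities(it, psi)
            assert np.all(p >= 0)
            assert np.sum(p) == pytest.approx(1.0, abs=1e-12)

    @given(psi=st.floats(-8, 8), dpsi=st.floats(0.01, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_psi(self, psi, dpsi):
        from ipssirt import reference

        it = reference.unidimensional_bank().items[2]
        for k in range(1, 6):
            assert ip.cumulative_probability(it, psi + dpsi, k) >= ip.cumulative_probability(
                it, psi, k
            )


class TestExpectedScore:
    def test_bounds_and_monotonicity(self, uni_bank):
        psi = np.linspace(-9, 9, 181)
        for it in uni_bank.items:
            e = ip.expected_score(it, psi)
            assert np.all((e >= 0) & (e <= 5))
            assert np.all(np.diff(e) > 0)

    def test_equals_weighted_sum_identity(self, uni_bank):
        psi = np.array([-3.0, 0.0, 2.5])
        for it in uni_bank.items:
            p = ip.category_probabilities(it, psi)
            manual = p @ np.arange(6)
            np.testing.assert_allclose(ip.expected_score(it, psi), manual, atol=1e-12)

    def test_nocturia_scores_nonzero_at_low_disability(self, uni_bank):
        # P(Y7 >= 1 | psi=-4) = logistic(0.49 * 3.89) ~ 0.87: even patients
        # with low disability usually wake at least once per night
        it7 = uni_bank.items[6]
        assert ip.cumulative_probability(it7, -4.0, 1) > 0.87
        assert ip.expected_score(it7, -4.0) > 0.87


class TestInformation:
    def test_dichotomous_closed_form(self):
        it = ItemParameters(index=1, discrimination=1.7, thresholds=(0.3,))
        # at psi = tau, P = 1/2 and the information is a^2 * P(1-P) = a^2/4
        assert ip.item_information(it, 0.3) == pytest.approx(1.7**2 / 4, rel=1e-10)

    def test_nonnegative_on_grid(self, uni_bank):
        grid = np.linspace(-8, 8, 321)
        for it in uni_bank.items:
            assert np.all(ip.item_information(it, grid) >= 0)

    def test_monte_carlo_observed_information(self, uni_bank):
        # the negative expected second derivative of the log-likelihood,
        # estimated by simulation, matches the analytic formula
        it = uni_bank.items[2]
        psi, h = 0.5, 1e-3
        rng = np.random.default_rng(4)
        y = simulate_item_scores(it, np.full(1_000_000, psi), rng)
        lp = {
            d: np.log(np.maximum(ip.category_probabilities(it, psi + d), 1e-300))[y]
            for d in (-h, 0.0, h)
        }
        d2 = (lp[h] - 2 * lp[0.0] + lp[-h]) / h**2
        assert -d2.mean() == pytest.approx(ip.item_information(it, psi), rel=0.02)


class TestResponseLoglik:
    def test_all_missing_is_zero(self, uni_bank):
        assert ip.response_loglik(uni_bank, 0.7, [None] * 7) == 0.0

    def test_single_item_definition(self, uni_bank):
        resp = [None, 3, None, None, None, None, None]
        expect = np.log(ip.category_probabilities(uni_bank.items[1], -0.4)[3])
        assert ip.response_loglik(uni_bank, -0.4, resp) == pytest.approx(expect)

    def test_matches_bruteforce_product(self, uni_bank):
        rng = np.random.default_rng(11)
        resp = rng.integers(0, 6, size=7)
        psi = 0.9
        manual = sum(
            np.log(ip.category_probabilities(it, psi)[r])
            for it, r in zip(uni_bank.items, resp)
        )
        assert ip.response_loglik(uni_bank, psi, resp) == pytest.approx(manual)

    def test_score_out_of_range_rejected(self, uni_bank):
        with pytest.raises(ValueError, match="outside"):
            ip.response_loglik(uni_bank, 0.0, [6, 0, 0, 0, 0, 0, 0])

    def test_bidimensional_equal_coordinates_match_unidimensional(self, bi_bank):
        # a bidimensional bank evaluated at identical latent coordinates is
        # the same likelihood as a unidimensional bank with those parameters
        from dataclasses import replace

        uni_items = tuple(replace(it, dimension="general") for it in bi_bank.items)
        uni = ItemBank(items=uni_items, n_dimensions=1)
        resp = [2, 1, 3, 0, 4, 2, 1]
        for psi in (-1.2, 0.0, 1.7):
            assert ip.response_loglik(bi_bank, [psi, psi], resp) == pytest.approx(
                ip.response_loglik(uni, psi, resp)
            )


class TestSimulation:
    def test_empirical_frequencies_match_exact_probabilities(self, uni_bank):
        it = uni_bank.items[3]
        psi = -0.8
        n = 100_000
        rng = np.random.default_rng(3)
        y = simulate_item_scores(it, np.full(n, psi), rng)
        p = ip.category_probabilities(it, psi)
        for k in range(6):
            freq = np.mean(y == k)
            se = np.sqrt(p[k] * (1 - p[k]) / n)
            assert abs(freq - p[k]) < 3 * se + 1e-9

    def test_validation_rejects_bad_items(self):
        with pytest.raises(ValueError, match="increasing"):
            ItemParameters(index=1, discrimination=1.0, thresholds=(0.0, -1.0))
        with pytest.raises(ValueError, match="discrimination"):
            ItemParameters(index=1, discrimination=-0.5, thresholds=(0.0,))
        with pytest.raises(ValueError, match="voiding"):
            items = tuple(
                ItemParameters(index=j, discrimination=1.0, thresholds=(0.0,),
                               dimension="storage")
                for j in range(1, 8)
            )
            ItemBank(items=items, n_dimensions=2)
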