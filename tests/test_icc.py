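"""IDVIS ICC estimation: reshaping, marginal likelihood, EBEs, shrinkage."""

import numpy as np
import pandas as pd
import pytest

import ipssirt as ip
from ipssirt.grm import ItemBank, ItemParameters
from ipssirt.icc import (
    GradedResponseMML,
    LatentShift,
    estimate_ebe,
    reassemble_idvis,
    reshape_idvis,
)


class TestLatentShift:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            LatentShift(post_mean=(0.0,), post_variance=(0.0,))
        with pytest.raises(ValueError, match="correlation"):
            LatentShift(post_mean=(0.0, 0.0), post_variance=(1.0, 1.0))
        with pytest.raises(ValueError, match="correlation"):
            LatentShift(post_mean=(0.0, 0.0), post_variance=(1.0, 1.0), correlation=1.2)

    def test_priors(self, bi_shift):
        mean, cov = bi_shift.prior("baseline")
        np.testing.assert_allclose(mean, [0, 0])
        np.testing.assert_allclose(np.diag(cov), [1, 1])
        assert cov[0, 1] == pytest.approx(0.691)
        mean, cov = bi_shift.prior("post")
        np.testing.assert_allclose(mean, [-1.07, -1.40])
        np.testing.assert_allclose(np.diag(cov), [1.61, 2.40])


class TestReshape:
    def test_counts_roundtrip_and_missing_visit(self, idvis_small):
        pseudo = reshape_idvis(idvis_small)
        assert len(pseudo) == 60 * 4
        assert (pseudo.loc[pseudo["time_months"] == 0, "origin"] == "baseline").all()
        assert (pseudo.loc[pseudo["time_months"] > 0, "origin"] == "post").all()
        back = reassemble_idvis(pseudo)
        pd.testing.assert_frame_equal(
            back, idvis_small.sort_values(["patient_id", "time_months"]).reset_index(drop=True)
        )
        # dropping one visit removes exactly that pseudo-individual
        drop = idvis_small.drop(index=5).reset_index(drop=True)
        pseudo2 = reshape_idvis(drop)
        assert len(pseudo2) == len(pseudo) - 1

    def test_duplicate_rows_rejected(self, idvis_small):
        dup = pd.concat([idvis_small, idvis_small.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            reshape_idvis(dup)


class TestParameterCounts:
    def test_unidimensional_44_and_bidimensional_47(self, idvis_small):
        m1 = GradedResponseMML(idvis_small, n_dimensions=1)
        m2 = GradedResponseMML(idvis_small, n_dimensions=2)
        assert m1._start().size == 44
        assert m2._start().size == 47


class TestMarginalLikelihood:
    def test_duplicated_rows_double_the_ofv(self, idvis_small, uni_bank, uni_shift):
        m = GradedResponseMML(idvis_small, n_dimensions=1)
        doubled = pd.concat(
            [idvis_small, idvis_small.assign(patient_id=idvis_small.patient_id + 1000)],
            ignore_index=True,
        )
        m2 = GradedResponseMML(doubled, n_dimensions=1)
        assert m2.ofv(uni_bank, uni_shift) == pytest.approx(
            2 * m.ofv(uni_bank, uni_shift), rel=1e-12
        )

    def test_adaptive_21_matches_nonadaptive_101_nodes(self, uni_bank, uni_shift):
        ds = ip.simulate_idvis_dataset(
            uni_bank, uni_shift, n_patients=25, visit_times=(0.0, 3.0), seed=33
        )
        m = GradedResponseMML(ds, n_dimensions=1, n_quad=21)
        ofv_adaptive = -2 * m.loglik(uni_bank, uni_shift, quadrature="adaptive")
        ofv_dense = -2 * m.loglik(uni_bank, uni_shift, n_quad=101)
        assert ofv_adaptive == pytest.approx(ofv_dense, abs=0.01)

    def test_baseline_only_data_warns(self, uni_bank, uni_shift):
        ds = ip.simulate_idvis_dataset(
            uni_bank, uni_shift, n_patients=20, visit_times=(0.0,), seed=8
        )
        with pytest.warns(UserWarning, match="not identified"):
            GradedResponseMML(ds, n_dimensions=1)


class TestFit:
    @pytest.fixture(scope="class")
    def small_fit(self, uni_bank, uni_shift):
        ds = ip.simulate_idvis_dataset(
            uni_bank, uni_shift, n_patients=150, visit_times=(0.0, 1.0, 3.0, 6.0),
            seed=55,
        )
        model = GradedResponseMML(ds, n_dimensions=1)
        return model, model.fit(compute_se=True, maxiter=400)

    def test_fit_beats_truth_ofv(self, small_fit, uni_bank, uni_shift):
        model, res = small_fit
        assert res.converged
        assert res.ofv <= model.ofv(uni_bank, uni_shift) + 1e-6
        assert res.k_params == 44
        assert res.aic == pytest.approx(res.ofv + 88)

    def test_loose_parameter_recovery_at_small_n(self, small_fit):
        # 600 pseudo-individuals: discriminations within about 30%, except
        # nocturia whose low slope (3% of the total information) leaves it
        # weakly identified at this size
        _, res = small_fit
        for j, true_a in zip(range(1, 7), (1.38, 0.98, 1.29, 0.92, 1.09, 0.95)):
            assert res.params[f"a{j}"] == pytest.approx(true_a, rel=0.35)
        assert res.params["a7"] == pytest.approx(0.49, rel=0.6)
        assert res.params["post_mean"] == pytest.approx(-1.38, abs=0.35)

    def test_standard_errors_sane(self, small_fit):
        _, res = small_fit
        se = res.se_table
        assert se is not None and (se.drop(index=[]) >= 0).all()
        # discrimination RSEs should be moderate at this size
        assert 0.01 < se["a1"] / res.params["a1"] < 0.5
        assert "Graded response" in res.summary()

    def test_bidimensional_nests_unidimensional(self, small_fit):
        # embed the unidimensional solution (correlation -> 1) as a start:
        # the fitted bidimensional model can only improve the OFV
        from dataclasses import replace

        model, res = small_fit
        items2 = tuple(
            replace(it, dimension="voiding" if it.index in (1, 3, 5, 6) else "storage")
            for it in res.item_bank.items
        )
        bank2 = ItemBank(items=items2, n_dimensions=2)
        shift2 = LatentShift(
            post_mean=(res.latent_shift.post_mean[0],) * 2,
            post_variance=(res.latent_shift.post_variance[0],) * 2,
            correlation=0.999,
        )
        m2 = GradedResponseMML(model.pseudo_table, n_dimensions=2, n_quad=7)
        embedded_ofv = m2.ofv(bank2, shift2)
        assert embedded_ofv == pytest.approx(res.ofv, rel=0.01)
        res2 = m2.fit(start=(bank2, shift2), maxiter=150, compute_se=False)
        assert res2.k_params == 47
        assert res2.ofv <= embedded_ofv + 0.1


class TestEbe:
    def test_no_items_returns_prior(self, uni_bank, uni_shift):
        ebe, se = estimate_ebe(uni_bank, uni_shift, [np.nan] * 7, "baseline")
        assert ebe[0] == pytest.approx(0.0, abs=1e-9)
        assert se[0] == pytest.approx(1.0, abs=1e-9)
        ebe, se = estimate_ebe(uni_bank, uni_shift, [np.nan] * 7, "post")
        assert ebe[0] == pytest.approx(-1.38)
        assert se[0] == pytest.approx(np.sqrt(2.22))

    def test_all_zero_pattern_below_prior_mean(self, uni_bank, uni_shift):
        ebe, _ = estimate_ebe(uni_bank, uni_shift, [0] * 7, "baseline")
        assert ebe[0] < 0

    def test_newton_matches_grid_search_oracle(self, uni_bank, uni_shift):
        rng = np.random.default_rng(17)
        grid = np.arange(-10, 10, 0.001)
        for _ in range(6):
            resp = rng.integers(0, 6, size=7)
            ebe, _ = estimate_ebe(uni_bank, uni_shift, resp, "post")
            ll = np.array([ip.response_loglik(uni_bank, g, resp) for g in grid])
            post = ll - 0.5 * (grid + 1.38) ** 2 / 2.22
            assert abs(ebe[0] - grid[np.argmax(post)]) < 0.01

    def test_bidimensional_ebe_with_missing_items(self, bi_bank, bi_shift):
        resp = [3, np.nan, 2, np.nan, 4, 1, np.nan]  # storage nearly unobserved
        ebe, se = estimate_ebe(bi_bank, bi_shift, resp, "baseline")
        assert se.shape == (2,)
        assert se[1] > se[0]  # less information on the storage coordinate
        # correlation still informs the storage estimate
        assert abs(ebe[1]) > 0


class TestShrinkage:
    def test_zero_when_ebes_equal_true_draws(self, uni_shift, idvis_full, idvis_full_ebe):
        pseudo, ebe = idvis_full_ebe
        perfect = ebe.copy()
        perfect["ebe"] = pseudo["psi"].to_numpy()
        perfect["se"] = 1e-6
        sh = ip.shrinkage(uni_shift, perfect)["general"]
        assert abs(sh["typical"]) < 0.05

    def test_uninformative_items_collapse_to_prior(self, uni_shift):
        items = tuple(
            ItemParameters(index=j, discrimination=1e-4,
                           thresholds=tuple(np.linspace(-2, 2, 5)))
            for j in range(1, 8)
        )
        bank = ItemBank(items=items, n_dimensions=1)
        ds = ip.simulate_idvis_dataset(bank, uni_shift, n_patients=40,
                                       visit_times=(0.0, 3.0), seed=3)
        pseudo = reshape_idvis(ds)
        est = ip.estimate_disability(bank, uni_shift, pseudo)
        sh = ip.shrinkage(uni_shift, est)["general"]
        assert sh["typical"] > 0.95

    def test_full_design_shrinkage_near_ten_percent(self, uni_shift, idvis_full_ebe):
        _, ebe = idvis_full_ebe
        sh = ip.shrinkage(uni_shift, ebe)["general"]
        assert sh["typical"] == pytest.approx(0.10, abs=0.03)
        lo, hi = sh["individual_range"]
        assert 0 < lo < hi < 1

    def test_requires_two_estimates(self, uni_shift, idvis_full_ebe):
        _, ebe = idvis_full_ebe
        with pytest.raises(ValueError, match="two"):
            ip.shrinkage(uni_shift, ebe.iloc[:1])
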