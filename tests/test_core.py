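import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timmrd as T
from timmrd.core import PanelLikelihood
from timmrd.errors import ConstraintError, ValidationError

from conftest import make_counts


class TestMixtureMean:
    def test_pure_background(self):
        assert T.mixture_mean(0, 0, 0.8, 0.3, 0.01) == pytest.approx(0.01)

    def test_pure_tumor_limit(self):
        eps = 1e-9
        assert T.mixture_mean(1 - eps, 0, 0.8, 0.3, 0.01) == pytest.approx(0.8, abs=1e-6)

    def test_arithmetic(self):
        assert T.mixture_mean(0.5, 0.25, 0.8, 0.4, 0.0) == pytest.approx(0.5)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ConstraintError):
            T.mixture_mean(0.6, 0.5, 0.8, 0.3, 0.01)

    @given(
        st.floats(0, 0.99), st.floats(0, 0.99),
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_result_in_unit_interval(self, a, g, bt, bn, b0):
        if a + g >= 1:
            a, g = a / 2, g / 2
        assert 0.0 <= T.mixture_mean(a, g, bt, bn, b0) <= 1.0


class TestBlockMarginal:
    def test_uniform_prior_is_discrete_uniform(self):
        # Beta(1,1) background with alpha=gamma=0: M ~ uniform on 0..N
        ll = T.block_marginal_loglik(0, 0, 10, 3, 0.5, 0.5, 1.0, 1.0)
        assert ll == pytest.approx(np.log(1 / 11), abs=1e-10)

    def test_matches_closed_form_beta_binomial(self):
        for m in range(6):
            ll = T.block_marginal_loglik(0, 0, 5, m, 0.8, 0.1, 2.0, 8.0)
            assert ll == pytest.approx(T.beta_binomial_logpmf(m, 5, 2.0, 8.0), abs=1e-8)

    def test_uncovered_block_contributes_zero(self):
        assert T.block_marginal_loglik(0.3, 0.2, 0, 0, 0.8, 0.1, 2.0, 8.0) == 0.0

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValidationError):
            T.block_marginal_loglik(0, 0, 5, 1, 0.8, 0.1, 0.0, 8.0)

    @given(
        st.floats(0, 0.5), st.floats(0, 0.4),
        st.floats(0.3, 1.0), st.floats(0, 0.3),
        st.sampled_from([0.5, 1.0, 2.0, 8.0]), st.sampled_from([0.5, 2.0, 8.0]),
        st.integers(1, 30),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_marginal_pmf_sums_to_one(self, a, g, bt, bn, p, q, n):
        total = sum(
            np.exp(T.block_marginal_loglik(a, g, n, m, bt, bn, p, q, 64))
            for m in range(n + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestTotalLoglik:
    def test_single_block_panel_equals_block_marginal(self, small_world):
        panel = small_world["panel"]
        prior = small_world["prior"]
        one = T.PatientPanel("P1", panel.blocks[:1])
        b = one.blocks[0]
        counts = make_counts({b.block_id: (20, 3)})
        expected = T.block_marginal_loglik(
            0.01, 0.1, 20, 3, b.beta_t, b.beta_n,
            prior[b.block_id].p, prior[b.block_id].q,
        )
        assert T.total_loglik(0.01, 0.1, one, counts, prior) == pytest.approx(expected)

    def test_block_order_invariance(self, small_world):
        panel, prior, spec = (
            small_world["panel"], small_world["prior"], small_world["spec"],
        )
        rng = np.random.default_rng(0)
        counts = T.simulate_plasma_mixture(
            0.02, 0.0, small_world["tumor"], small_world["normal"], prior, spec, rng
        )
        value = T.total_loglik(0.01, 0.1, panel, counts, prior)
        reversed_panel = T.PatientPanel("P1", panel.blocks[::-1])
        assert T.total_loglik(0.01, 0.1, reversed_panel, counts, prior) == pytest.approx(value)

    def test_matches_high_resolution_quadrature_oracle(self, small_world):
        # independent check at 10x the default quadrature order
        panel, prior, spec = (
            small_world["panel"], small_world["prior"], small_world["spec"],
        )
        rng = np.random.default_rng(1)
        counts = T.simulate_plasma_mixture(
            0.01, 0.1, small_world["tumor"], small_world["normal"], prior, spec, rng
        )
        fast = T.total_loglik(0.01, 0.1, panel, counts, prior)
        slow = T.total_loglik(
            0.01, 0.1, panel, counts, prior, T.ScoringOptions(quad_order=1280)
        )
        assert fast == pytest.approx(slow, abs=1e-6)

    def test_empty_panel_rejected(self, small_world):
        with pytest.raises(ValidationError):
            T.total_loglik(
                0, 0, T.PatientPanel("P"), make_counts({}), small_world["prior"]
            )

    def test_gradient_matches_finite_differences(self, small_world):
        panel, prior, spec = (
            small_world["panel"], small_world["prior"], small_world["spec"],
        )
        rng = np.random.default_rng(4)
        counts = T.simulate_plasma_mixture(
            0.03, 0.05, small_world["tumor"], small_world["normal"], prior, spec, rng
        )
        pl = PanelLikelihood(panel, prior)
        n, m = pl.sample_arrays(counts)
        a0, g0, h = 0.02, 0.08, 1e-6
        _, grad = pl.loglik_grad(a0, g0, n, m)
        fd_a = (pl.loglik(a0 + h, g0, n, m) - pl.loglik(a0 - h, g0, n, m)) / (2 * h)
        fd_g = (pl.loglik(a0, g0 + h, n, m) - pl.loglik(a0, g0 - h, n, m)) / (2 * h)
        assert grad[0] == pytest.approx(fd_a, rel=1e-5)
        assert grad[1] == pytest.approx(fd_g, rel=1e-5)


class TestThresholdAndCall:
    def test_default_threshold_is_chi2_98th_quantile(self):
        assert round(T.classification_threshold(0.98), 3) == 5.412

    def test_median_of_chi2(self):
        assert T.classification_threshold(0.5) == pytest.approx(0.455, abs=5e-4)

    def test_threshold_vanishes_at_low_percentile(self):
        assert T.classification_threshold(1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range_percentile_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.7):
            with pytest.raises(ValidationError):
                T.classification_threshold(bad)

    def test_observed_patient_scores_classify_correctly(self):
        # postoperative samples of one relapsing patient: 7.978 exceeds the
        # threshold, 4.244 does not
        thr = T.classification_threshold(0.98)
        assert T.classify(7.978, thr) == "high"
        assert T.classify(4.244, thr) == "low"

    def test_boundary_is_low(self):
        assert T.classify(5.412, 5.412) == "low"

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            T.classify(-1.0, 5.412)


class TestFit:
    def test_null_data_scores_low(self, small_world):
        spec, prior = small_world["spec"], small_world["prior"]
        rng = np.random.default_rng(8)
        n_low = 0
        for _ in range(20):
            counts = T.simulate_plasma_mixture(
                0.0, 0.0, small_world["tumor"], small_world["normal"], prior, spec, rng
            )
            fit = T.fit_timmrd(small_world["panel"], counts, prior)
            n_low += fit.call == "low" and fit.alpha_hat < 0.01
        assert n_low >= 19

    def test_strong_signal_scores_far_above_threshold(self, small_world):
        spec, prior = small_world["spec"], small_world["prior"]
        rng = np.random.default_rng(9)
        counts = T.simulate_plasma_mixture(
            0.2, 0.0, small_world["tumor"], small_world["normal"], prior, spec, rng
        )
        fit = T.fit_timmrd(small_world["panel"], counts, prior)
        assert fit.score > 10 * 5.412
        assert fit.call == "high"
        assert fit.alpha_hat == pytest.approx(0.2, abs=0.05)

    def test_constraints_hold_exactly(self, small_world):
        spec, prior = small_world["spec"], small_world["prior"]
        rng = np.random.default_rng(10)
        for a_true in (0.0, 0.05, 0.6):
            counts = T.simulate_plasma_mixture(
                a_true, 0.2, small_world["tumor"], small_world["normal"], prior, spec, rng
            )
            fit = T.fit_timmrd(small_world["panel"], counts, prior)
            assert fit.alpha_hat >= 0
            assert fit.gamma_hat >= 0
            assert fit.alpha_hat + fit.gamma_hat < 1
            assert fit.loglik_full >= fit.loglik_null - 1e-9
            assert fit.score >= 0
            if fit.alpha_hat == 0:
                assert fit.score == 0

    def test_deterministic_for_fixed_inputs(self, small_world):
        spec, prior = small_world["spec"], small_world["prior"]
        rng = np.random.default_rng(12)
        counts = T.simulate_plasma_mixture(
            0.03, 0.0, small_world["tumor"], small_world["normal"], prior, spec, rng
        )
        f1 = T.fit_timmrd(small_world["panel"], counts, prior)
        f2 = T.fit_timmrd(small_world["panel"], counts, prior)
        assert (f1.alpha_hat, f1.gamma_hat, f1.score) == (f2.alpha_hat, f2.gamma_hat, f2.score)

    def test_no_coverage_rejected(self, small_world):
        with pytest.raises(ValidationError):
            T.fit_timmrd(small_world["panel"], make_counts({}), small_world["prior"])

    def test_wald_score_zero_at_boundary(self):
        score, se = T.wald_score(lambda a, g: 0.0, lambda a, g: np.zeros(2), 0.0, 0.1)
        assert score == 0.0
        assert se is None

    def test_wald_agrees_with_likelihood_ratio_asymptotically(self):
        # at moderate alpha with a deep, wide panel the Wald statistic and
        # 2*(l_full - l_null) should nearly coincide
        spec = T.SimulationSpec(n_blocks=500, n_dmb_true=500, seed=7, depth_mean=200.0)
        prior = T.true_background_prior(spec)
        tumor, normal, planted = T.simulate_tissue_pair(spec, prior)
        panel = T.PatientPanel(
            "P1", [T.PanelBlock(b, tumor.level(b), normal.level(b)) for b in sorted(planted)]
        )
        rng = np.random.default_rng(3)
        rel = []
        for _ in range(3):
            counts = T.simulate_plasma_mixture(0.05, 0.0, tumor, normal, prior, spec, rng)
            fit = T.fit_timmrd(panel, counts, prior)
            lrt = 2 * (fit.loglik_full - fit.loglik_null)
            rel.append(abs(fit.score / lrt - 1))
        assert max(rel) < 0.05

    def test_mean_score_monotone_in_tumor_fraction(self):
        # echoes the simulation finding that the score tracks the simulated
        # tumor fraction; run in the deep low-background regime where even
        # a 1e-4 fraction carries measurable signal
        spec = T.SimulationSpec(
            n_blocks=200, n_dmb_true=200, seed=21, depth_mean=4000.0,
            p_range=(0.3, 1.0), q_range=(500.0, 2000.0),
        )
        prior = T.true_background_prior(spec)
        tumor, normal, planted = T.simulate_tissue_pair(spec, prior)
        panel = T.PatientPanel(
            "P", [T.PanelBlock(b, tumor.level(b), normal.level(b)) for b in sorted(planted)]
        )
        fractions = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
        means = []
        for frac in fractions:
            rng = np.random.default_rng(100)
            scores = [
                T.fit_timmrd(
                    panel,
                    T.simulate_plasma_mixture(frac, 0.0, tumor, normal, prior, spec, rng),
                    prior,
                ).score
                for _ in range(100)
            ]
            means.append(float(np.mean(scores)))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:])), means


class TestGridOracle:
    def test_flat_likelihood_when_panel_uninformative(self):
        # tissue levels equal to a near-degenerate prior mean: the grid
        # surface is constant in (alpha, gamma) up to numerical tolerance
        from timmrd.background_prior import PriorEntry

        mean = 0.3
        conc = 1e9
        prior = T.BackgroundPrior(
            {"b1": PriorEntry(mean * conc, (1 - mean) * conc, 10, "moments")}
        )
        panel = T.PatientPanel("P", [T.PanelBlock("b1", mean, mean)])
        counts = make_counts({"b1": (50, 15)})
        pl = PanelLikelihood(panel, prior)
        n, m = pl.sample_arrays(counts)
        grid = pl.loglik_grid(
            np.array([0.0, 0.2, 0.5]), np.array([0.0, 0.3, 0.1]), n, m
        )
        assert np.ptp(grid) < 1e-6
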