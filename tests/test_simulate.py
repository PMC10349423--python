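import numpy as np
import pytest

import timmrd as T
from timmrd.core import PanelLikelihood
from timmrd.errors import ConstraintError, ValidationError


class TestTissuePair:
    def test_planted_block_bookkeeping(self):
        spec = T.SimulationSpec(n_blocks=1000, n_dmb_true=50, seed=1)
        _, _, planted = T.simulate_tissue_pair(spec)
        assert len(planted) == 50

    def test_seed_determinism(self):
        spec = T.SimulationSpec(n_blocks=100, n_dmb_true=10, seed=3)
        t1, n1, p1 = T.simulate_tissue_pair(spec)
        t2, n2, p2 = T.simulate_tissue_pair(spec)
        assert p1 == p2
        assert t1.levels == t2.levels
        assert n1.levels == n2.levels

    def test_null_tissue_has_no_planted_signal(self):
        spec = T.SimulationSpec(n_blocks=200, n_dmb_true=0, seed=2, normal_noise_sd=0.01)
        tumor, normal, planted = T.simulate_tissue_pair(spec)
        assert planted == set()
        diffs = [
            abs(tumor.level(b) - normal.level(b)) for b in tumor.levels
        ]
        assert max(diffs) < 6 * 0.01

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            T.SimulationSpec(n_blocks=10, n_dmb_true=20)


class TestHealthyPlasma:
    def test_ratio_means_match_prior_means(self):
        spec = T.SimulationSpec(n_blocks=30, n_dmb_true=0, seed=4, depth_mean=200.0)
        healthy, prior = T.simulate_healthy_plasma(spec, 200)
        for block_id in list(prior.entries)[:10]:
            ratios = np.array(
                [m / n for s in healthy for (n, m) in [s.get(block_id)] if n > 0]
            )
            mu = prior[block_id].mean
            e = prior[block_id]
            prior_var = mu * (1 - mu) / (e.p + e.q + 1)
            se = np.sqrt((prior_var + mu / 200) / len(ratios))
            assert abs(ratios.mean() - mu) < 3 * se + 1e-3

    def test_depth_model_mean(self):
        spec = T.SimulationSpec(n_blocks=200, n_dmb_true=0, seed=5, depth_mean=200.0)
        healthy, _ = T.simulate_healthy_plasma(spec, 20)
        depths = np.array([n for s in healthy for (n, _) in s.counts.values()])
        assert abs(depths.mean() - 200.0) / 200.0 < 0.05

    def test_single_sample(self):
        spec = T.SimulationSpec(n_blocks=10, n_dmb_true=0, seed=6)
        healthy, _ = T.simulate_healthy_plasma(spec, 1)
        assert len(healthy) == 1

    def test_counts_within_bounds(self):
        spec = T.SimulationSpec(n_blocks=100, n_dmb_true=0, seed=7)
        healthy, _ = T.simulate_healthy_plasma(spec, 5)
        for s in healthy:
            assert all(0 <= m <= n for n, m in s.counts.values())


class TestPlasmaMixture:
    def test_zero_mixture_reduces_to_healthy(self):
        spec = T.SimulationSpec(n_blocks=50, n_dmb_true=5, seed=8)
        prior = T.true_background_prior(spec)
        tumor, normal, _ = T.simulate_tissue_pair(spec, prior)
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        empty_t = T.TissueMethylome("z", "tumor")
        empty_n = T.TissueMethylome("z", "adjacent_normal")
        for b in prior.entries:
            empty_t.add(b, 0.0, 1)
            empty_n.add(b, 0.0, 1)
        mix = T.simulate_plasma_mixture(0.0, 0.0, tumor, normal, prior, spec, rng1)
        ref = T.simulate_plasma_mixture(0.0, 0.0, empty_t, empty_n, prior, spec, rng2)
        assert mix.counts == ref.counts

    def test_tumor_limit_concentrates_at_tumor_levels(self):
        spec = T.SimulationSpec(n_blocks=50, n_dmb_true=50, seed=9, depth_mean=5000.0)
        prior = T.true_background_prior(spec)
        tumor, normal, planted = T.simulate_tissue_pair(spec, prior)
        rng = np.random.default_rng(1)
        mix = T.simulate_plasma_mixture(0.999, 0.0, tumor, normal, prior, spec, rng)
        for b in sorted(planted)[:10]:
            n, m = mix.get(b)
            assert abs(m / n - tumor.level(b)) < 0.05

    def test_expected_ratio_at_small_fraction(self):
        # alpha=0.01 against beta_t=0.8 over a 0.01 background: expected
        # plasma level 0.99*0.01 + 0.01*0.8 = 0.0179
        from timmrd.background_prior import PriorEntry

        prior = T.BackgroundPrior(
            {f"b{j}": PriorEntry(10.0, 990.0, 0, "moments") for j in range(200)}
        )
        spec = T.SimulationSpec(n_blocks=200, n_dmb_true=0, seed=10, depth_mean=10_000.0)
        tumor = T.TissueMethylome("t", "tumor")
        normal = T.TissueMethylome("n", "adjacent_normal")
        for b in prior.entries:
            tumor.add(b, 0.8, 1)
            normal.add(b, 0.01, 1)
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(5):
            mix = T.simulate_plasma_mixture(0.01, 0.0, tumor, normal, prior, spec, rng)
            ratios.extend(m / n for n, m in mix.counts.values() if n > 0)
        assert np.mean(ratios) == pytest.approx(0.0179, abs=0.0005)

    def test_infeasible_mixture_rejected(self):
        spec = T.SimulationSpec(n_blocks=10, n_dmb_true=0, seed=1)
        prior = T.true_background_prior(spec)
        tumor, normal, _ = T.simulate_tissue_pair(spec, prior)
        with pytest.raises(ConstraintError):
            T.simulate_plasma_mixture(0.7, 0.4, tumor, normal, prior, spec)

    def test_generative_likelihood_self_consistency(self):
        # the scorer's likelihood prefers the true (alpha, gamma) over a
        # displaced one on average across replicates
        spec = T.SimulationSpec(n_blocks=100, n_dmb_true=100, seed=12, depth_mean=200.0)
        prior = T.true_background_prior(spec)
        tumor, normal, planted = T.simulate_tissue_pair(spec, prior)
        panel = T.PatientPanel(
            "P", [T.PanelBlock(b, tumor.level(b), normal.level(b)) for b in sorted(planted)]
        )
        pl = PanelLikelihood(panel, prior)
        rng = np.random.default_rng(13)
        a_true, g_true = 0.05, 0.1
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            counts = T.simulate_plasma_mixture(
                a_true, g_true, tumor, normal, prior, spec, rng
            )
            n, m = pl.sample_arrays(counts)
            at_truth = pl.loglik(a_true, g_true, n, m)
            displaced = pl.loglik(a_true + 0.05, g_true, n, m)
            wins += at_truth > displaced
        assert wins / n_rep > 0.95


class TestDilutionSeries:
    def test_bookkeeping(self):
        spec = T.SimulationSpec(n_blocks=20, n_dmb_true=5, seed=14)
        series = T.simulate_dilution_series([0.1, 0.0], 5, spec)
        assert len(series.samples) == 10
        assert sorted({f for f, _ in series.samples}) == [0.0, 0.1]

    def test_determinism(self):
        spec = T.SimulationSpec(n_blocks=20, n_dmb_true=5, seed=15)
        s1 = T.simulate_dilution_series([0.01], 3, spec)
        s2 = T.simulate_dilution_series([0.01], 3, spec)
        for (f1, c1), (f2, c2) in zip(s1.samples, s2.samples):
            assert f1 == f2 and c1.counts == c2.counts


class TestLongitudinalCohort:
    def test_no_relapse_cohort_is_all_clean(self):
        lspec = T.LongitudinalSpec(n_patients=5, relapse_fraction=0.0, seed=1)
        spec = T.SimulationSpec(n_blocks=20, n_dmb_true=5, seed=1, depth_mean=50.0)
        patients, _ = T.simulate_longitudinal_cohort(lspec, spec)
        for p in patients:
            assert not p.relapsed and p.relapse_day is None
            for s in p.samples:
                if s.day_from_surgery > 30:
                    assert p.true_alpha[s.sample_id] == 0.0

    def test_fixed_seed_reproduces_cohort(self):
        lspec = T.LongitudinalSpec(n_patients=3, seed=2)
        spec = T.SimulationSpec(n_blocks=15, n_dmb_true=5, seed=2, depth_mean=50.0)
        p1, _ = T.simulate_longitudinal_cohort(lspec, spec)
        p2, _ = T.simulate_longitudinal_cohort(lspec, spec)
        for a, b in zip(p1, p2):
            assert a.relapsed == b.relapsed and a.relapse_day == b.relapse_day
            assert a.true_alpha == b.true_alpha
            for ca, cb in zip(a.counts, b.counts):
                assert ca.counts == cb.counts
            assert [s.max_af for s in a.samples] == [s.max_af for s in b.samples]

    def test_relapse_signal_regrows_before_relapse_day(self):
        lspec = T.LongitudinalSpec(n_patients=30, relapse_fraction=1.0, seed=3)
        spec = T.SimulationSpec(n_blocks=15, n_dmb_true=5, seed=3, depth_mean=50.0)
        patients, _ = T.simulate_longitudinal_cohort(lspec, spec)
        for p in patients:
            post = [s for s in p.samples if s.day_from_surgery > 40]
            if not post:
                continue
            last = post[-1]
            # within ~one time constant of relapse the true fraction is material
            if p.relapse_day - last.day_from_surgery < lspec.regrowth_tau_days:
                assert p.true_alpha[last.sample_id] > 0.01

    def test_maxaf_floor_applies(self):
        lspec = T.LongitudinalSpec(n_patients=20, seed=4)
        spec = T.SimulationSpec(n_blocks=15, n_dmb_true=5, seed=4, depth_mean=50.0)
        patients, _ = T.simulate_longitudinal_cohort(lspec, spec)
        afs = [s.max_af for p in patients for s in p.samples]
        assert all(af == 0.0 or af >= lspec.maxaf_floor for af in afs)

    def test_unordered_days_rejected(self):
        with pytest.raises(ValidationError):
            T.LongitudinalSpec(day_b=50, day_c=36)
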