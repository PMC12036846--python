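"""Hierarchical KU sampler, KT grid fit and diagnostics tests."""

import numpy as np
import pandas as pd
import pytest

from socialdiscount.design import generative_pairs, make_uniform_targets
from socialdiscount.fitting import (
    HierarchicalKUModel,
    KTGridModel,
    MCMCConfig,
    PriorSpec,
    _sample_ku,
    fit_kt_grid,
    fit_ku_hierarchical,
    posterior_summary,
    rhat,
)

from conftest import simulate_ku_trials


class TestRhat:
    def test_constant_chains_convention(self):
        assert rhat(np.ones((4, 100))) == 1.0

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        r = rhat(rng.standard_normal((4, 2000)))
        assert 0.999 <= r <= 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 500))
        x[1] += 10
        assert rhat(x) > 1.1

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal((4, 400)), axis=1) * 0.05
        x += rng.standard_normal((4, 400))
        ours = rhat(x)
        theirs = float(az.rhat(az.convert_to_dataset(x[:, :, None])).x.values.item())
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestHierarchicalKU:
    def test_subject_level_recovery_on_repeated_subject(self, ladder_50):
        # 30 clones of one (km, ku) = (-2, 0.5) subject, 200 trials each:
        # group-mean posterior should sit near the truth
        rng = np.random.default_rng(10)
        pairs = ladder_50 * 4  # 200 trials
        trials = simulate_ku_trials([-2.0] * 30, [0.5] * 30, pairs, rng)
        m = HierarchicalKUModel(chains=4, warmup=600, draws=600, seed=5).fit(trials)
        mu_km = m.posterior_.draws["mu_km"].mean()
        mu_ku = m.posterior_.draws["mu_ku"].mean()
        assert abs(mu_km - (-2.0)) < 0.2
        assert abs(mu_ku - 0.5) < 0.2

    def test_constraints_respected_in_draws(self, ladder_50):
        rng = np.random.default_rng(11)
        trials = simulate_ku_trials([-2.5, -1.0, -0.5], [0.3, 0.6, 0.9], ladder_50, rng)
        m = HierarchicalKUModel(chains=2, warmup=200, draws=200, seed=1).fit(trials)
        assert np.all(m.posterior_.draws["km"] < 0)
        assert np.all(m.posterior_.draws["ku"] > 0)

    def test_choice_direction_drives_km(self, ladder_50):
        # an all-SS chooser ends near the impulsive boundary relative to
        # an all-LL chooser
        n = len(ladder_50)
        trials = pd.DataFrame(
            {
                "subject_id": ["allSS"] * n + ["allLL"] * n,
                "ss_amount": [p.ss.amount for p in ladder_50] * 2,
                "ll_amount": [p.ll.amount for p in ladder_50] * 2,
                "delay_days": [p.ll.delay for p in ladder_50] * 2,
                "choice": ["SS"] * n + ["LL"] * n,
            }
        )
        m = HierarchicalKUModel(chains=2, warmup=300, draws=300, seed=2).fit(trials)
        assert m.km_mean_["allSS"] > m.km_mean_["allLL"]

    def test_group_label_is_metadata_only(self, ladder_50):
        rng = np.random.default_rng(12)
        trials = simulate_ku_trials([-2.0, -1.2], [0.4, 0.6], ladder_50, rng)
        a = fit_ku_hierarchical(trials, mcmc_config=MCMCConfig(2, 200, 200), seed=3,
                                group_label="A")
        b = fit_ku_hierarchical(trials, mcmc_config=MCMCConfig(2, 200, 200), seed=3,
                                group_label="B")
        assert np.array_equal(a.draws["km"], b.draws["km"])

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            HierarchicalKUModel().fit(pd.DataFrame(columns=["subject_id", "choice"]))

    def test_summary_layout(self, ladder_50):
        rng = np.random.default_rng(13)
        trials = simulate_ku_trials([-2.0, -1.2, -0.7], [0.4, 0.6, 0.5], ladder_50, rng)
        gp = fit_ku_hierarchical(trials, mcmc_config=MCMCConfig(2, 200, 200), seed=4)
        summ = posterior_summary(gp)
        assert len(summ) == 3 * 2  # subjects x parameters
        assert ((summ["q2.5"] <= summ["mean"]) & (summ["mean"] <= summ["q97.5"])).all()

    def test_prior_only_sampling_reproduces_hyperpriors(self):
        # with the likelihood switched off, group-mean draws must match
        # the N(0, 3) hyperprior and group SDs the half-Cauchy(0, 2)
        x = np.zeros((3, 1))
        y = np.zeros((3, 1), dtype=bool)
        mask = np.zeros((3, 1), dtype=bool)  # no observations at all
        draws, _ = _sample_ku(
            x, y, mask, PriorSpec(), MCMCConfig(chains=4, warmup=2000, iters=4000),
            seed=123,
        )
        mu = draws["mu_km"].ravel()
        sig = draws["sigma_km"].ravel()
        assert abs(mu.mean()) < 0.35
        assert abs(mu.std() - 3.0) < 0.45
        # half-Cauchy(0, 2): median 2, quartiles ~0.83 / ~4.83
        assert abs(np.median(sig) - 2.0) < 0.7


class TestKTGrid:
    def test_recovery_median_within_tolerance(self):
        from socialdiscount.agents import simulate_choice_kt

        pairs = generative_pairs(make_uniform_targets(50))
        rng = np.random.default_rng(30)
        errs = []
        for _ in range(50):
            decisions = [
                (p, simulate_choice_kt(p, (-2.0, 0.5), rng)) for p in pairs
            ]
            params, _ = fit_kt_grid(decisions)
            errs.append(abs(params.k - (-2.0)))
        assert np.median(errs) <= 0.3

    def test_single_trial_posterior_proper(self):
        pair = generative_pairs([-2.0])[0]
        params, model = fit_kt_grid([(pair, "LL")])
        assert -4.0 <= params.k <= 0.0
        assert model.posterior_grid_.sum() == pytest.approx(1.0)

    def test_estimate_tracks_agent_patience(self):
        from socialdiscount.agents import correct_choice

        pairs = generative_pairs(make_uniform_targets(25))
        patient = [(p, correct_choice(p, -2.5)) for p in pairs]
        impulsive = [(p, correct_choice(p, -1.5)) for p in pairs]
        k_pat, _ = fit_kt_grid(patient)
        k_imp, _ = fit_kt_grid(impulsive)
        assert k_pat.k < -2.0 < k_imp.k

    def test_empty_decisions_rejected(self):
        with pytest.raises(ValueError):
            KTGridModel().fit([])


class TestSimulationBasedCalibration:
    def test_rank_uniformity_of_true_km(self):
        # 20 datasets drawn from the model's own prior: the rank of the
        # true subject-level km within its posterior draws is uniform
        from scipy.stats import chisquare, truncnorm

        pairs = generative_pairs(make_uniform_targets(30))
        rng = np.random.default_rng(77)
        ranks = []
        n_bins = 4
        for _ in range(20):
            mu_km = rng.normal(0, 3)
            sig_km = abs(2 * rng.standard_cauchy())
            mu_ku = rng.normal(0, 3)
            sig_ku = abs(2 * rng.standard_cauchy())
            km = truncnorm.rvs(-np.inf, (0 - mu_km) / sig_km, loc=mu_km,
                               scale=sig_km, size=6, random_state=rng)
            ku = truncnorm.rvs((0 - mu_ku) / sig_ku, np.inf, loc=mu_ku,
                               scale=sig_ku, size=6, random_state=rng)
            trials = simulate_ku_trials(km, ku, pairs, rng)
            m = HierarchicalKUModel(chains=2, warmup=400, draws=400,
                                    seed=int(rng.integers(2**31 - 1))).fit(trials)
            draws = m.posterior_.draws["km"][:, ::20, 0].ravel()  # thinned
            ranks.append((draws < km[0]).mean())
        counts = np.histogram(ranks, bins=np.linspace(0, 1, n_bins + 1))[0]
        stat, p = chisquare(counts)
        assert p > 0.01
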