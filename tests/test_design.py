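"""Pair enumeration, generative/adaptive design and scheduling tests."""

import numpy as np
import pytest

from socialdiscount.agents import simulate_choice_kt
from socialdiscount.core import ChoicePair, MonetaryOption
from socialdiscount.design import (
    BLOCK_LABELS,
    BeliefGrid,
    adaptive_next_pair,
    belief_init,
    belief_mean,
    belief_update,
    build_schedule,
    enumerate_pairs,
    generative_pairs,
    make_uniform_targets,
    pair_pool_arrays,
)


class TestEnumeration:
    def test_exhaustive_count(self):
        # C(20, 2) amount pairs x 90 delays
        assert len(enumerate_pairs()) == 190 * 90 == 17_100

    def test_known_pair_present_with_rate(self):
        target = ChoicePair(MonetaryOption(10, 0), MonetaryOption(20, 10))
        pool = enumerate_pairs()
        match = [p for p in pool if p == target]
        assert len(match) == 1 and match[0].indifference_logk == -1.0

    def test_all_pairs_valid(self):
        ss, ll, delay, logk = pair_pool_arrays()
        assert np.all(ll > ss) and np.all(delay >= 1) and np.all(np.isfinite(logk))


class TestGenerativeDesign:
    def test_uniform_targets(self):
        assert list(make_uniform_targets(2)) == [-4.0, 0.0]
        assert list(make_uniform_targets(5)) == [-4.0, -3.0, -2.0, -1.0, 0.0]
        spacing = np.diff(make_uniform_targets(25))
        assert np.allclose(spacing, 4 / 24)
        with pytest.raises(ValueError):
            make_uniform_targets(1)

    def test_exact_target_achieved(self):
        (pair,) = generative_pairs([-1.0])
        assert pair.indifference_logk == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        # fast nearest-rate search agrees with exhaustive scan + tie rule
        _, _, _, logk = pair_pool_arrays()
        pool = enumerate_pairs()
        rng = np.random.default_rng(3)
        targets = rng.uniform(-4.5, 0.5, 40)
        fast = generative_pairs(targets)
        for t, got in zip(targets, fast):
            diff = np.abs(logk - t)
            best = diff.min()
            ties = [pool[i] for i in np.flatnonzero(diff == best)]
            oracle = min(ties, key=lambda p: (p.ll.delay, p.ll.amount, p.ss.amount))
            assert got == oracle

    def test_gap_bounded_by_achievable_spacing(self):
        _, _, _, logk = pair_pool_arrays()
        achievable = np.sort(np.unique(logk))
        max_gap = np.diff(achievable).max() / 2
        pairs = generative_pairs(make_uniform_targets(25))
        for t, p in zip(make_uniform_targets(25), pairs):
            lo, hi = achievable[0], achievable[-1]
            if lo <= t <= hi:
                assert abs(p.indifference_logk - t) <= max_gap + 1e-12

    def test_membership_in_pool(self):
        pool = set(enumerate_pairs())
        for p in generative_pairs(make_uniform_targets(50)):
            assert p in pool


class TestBelief:
    def test_init_moments_and_mass(self):
        b = belief_init()
        assert b.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert belief_mean(b) == pytest.approx(-2.0, abs=1e-6)
        # symmetric tails of the N(-2, 1) prior
        below = b.mass[b.grid < -3].sum()
        above = b.mass[b.grid > -1].sum()
        assert below == pytest.approx(above, abs=1e-6)

    def test_init_requires_positive_sd(self):
        with pytest.raises(ValueError):
            belief_init(sd=0.0)

    def test_update_matches_bruteforce_bayes(self):
        from scipy.special import expit

        b = belief_init()
        pair = ChoicePair(MonetaryOption(10, 0), MonetaryOption(20, 10))
        updated = belief_update(b, pair, "LL")
        # independent dense Bayes computation
        K = 10.0**b.grid
        v_ll = pair.ll.amount / (1 + K * pair.ll.delay)
        like = expit((10**0.3) * (v_ll - pair.ss.amount))
        expected = b.mass * like
        expected /= expected.sum()
        assert np.allclose(updated.mass, expected, atol=1e-14)

    def test_ll_choice_moves_mean_toward_patience(self):
        b = belief_init()
        pair = ChoicePair(MonetaryOption(10, 0), MonetaryOption(20, 10))
        assert belief_mean(belief_update(b, pair, "LL")) < belief_mean(b)
        assert belief_mean(belief_update(b, pair, "SS")) > belief_mean(b)

    def test_sequential_equals_batch_bayes(self):
        # posterior from one-at-a-time updates == single dense product,
        # for 100 random decision sequences
        from scipy.special import expit

        rng = np.random.default_rng(11)
        pool = enumerate_pairs()
        for _ in range(100):
            b = belief_init()
            n = rng.integers(3, 12)
            idx = rng.integers(0, len(pool), n)
            choices = rng.choice(["SS", "LL"], n)
            seq = b
            batch_like = np.ones_like(b.mass)
            for i, c in zip(idx, choices):
                pair = pool[i]
                seq = belief_update(seq, pair, c)
                K = 10.0**b.grid
                v_ll = pair.ll.amount / (1 + K * pair.ll.delay)
                p_ll = expit((10**b.t_fixed) * (v_ll - pair.ss.amount))
                batch_like *= p_ll if c == "LL" else 1 - p_ll
            batch = b.mass * batch_like
            batch /= batch.sum()
            assert np.abs(seq.mass - batch).max() < 1e-10

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        pool = enumerate_pairs()
        decisions = [(pool[i], c) for i, c in zip(rng.integers(0, 17100, 8),
                                                  rng.choice(["SS", "LL"], 8))]
        b1 = belief_init()
        b2 = belief_init()
        for pair, c in decisions:
            b1 = belief_update(b1, pair, c)
        for pair, c in reversed(decisions):
            b2 = belief_update(b2, pair, c)
        assert np.allclose(b1.mass, b2.mass, atol=1e-12)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            BeliefGrid(grid=np.array([0.0, 0.0, 1.0]), mass=np.ones(3) / 3)
        with pytest.raises(ValueError):
            BeliefGrid(grid=np.array([0.0, 1.0]), mass=np.array([0.9, 0.2]))


class TestAdaptiveDesign:
    def test_targets_posterior_mean(self):
        b = belief_init()  # mean -2
        pair = adaptive_next_pair(b)
        _, _, _, logk = pair_pool_arrays()
        best = np.abs(logk - belief_mean(b)).min()
        assert abs(pair.indifference_logk - belief_mean(b)) == pytest.approx(best)

    def test_deterministic(self):
        b = belief_init(mean=-1.3)
        assert adaptive_next_pair(b) == adaptive_next_pair(b)

    def test_estimate_error_shrinks_with_trials(self):
        # adaptive probing of a KT agent: median |posterior mean - k*|
        # over 50 replicates decreases from trial 5 to trial 25
        rng = np.random.default_rng(21)
        err5, err25 = [], []
        for _ in range(50):
            k_true = rng.uniform(-3, -0.5)
            b = belief_init()
            for t in range(25):
                pair = adaptive_next_pair(b)
                choice = simulate_choice_kt(pair, (k_true, 0.3), rng)
                b = belief_update(b, pair, choice)
                if t == 4:
                    err5.append(abs(belief_mean(b) - k_true))
            err25.append(abs(belief_mean(b) - k_true))
        assert np.median(err25) < np.median(err5)


class TestSchedule:
    def test_shape_and_tags(self):
        s = build_schedule(seed=0)
        f = s.frame
        assert len(f) == 250
        assert list(f["block_label"].unique()) == list(BLOCK_LABELS)
        for b in (1, 3, 5):
            tags = f[f["block"] == b]["design_tag"].value_counts()
            assert tags["generative"] == 25 and tags["adaptive"] == 25
        for b in (2, 4):
            sub = f[f["block"] == b]
            assert (sub["design_tag"] == "generative").all()
            assert sorted(sub["target"]) == pytest.approx(
                list(make_uniform_targets(50))
            )

    def test_seed_reproducibility(self):
        a = build_schedule(seed=7).frame
        b = build_schedule(seed=7).frame
        c = build_schedule(seed=8).frame
        assert a.equals(b)
        assert not a.equals(c)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(other_order="whatever")
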