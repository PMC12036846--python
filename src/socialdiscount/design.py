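"""Choice-pair construction and session scheduling.

Pairs for the self-report blocks come from two interleaved sources:

* **generative** — the full grid of every admissible (smaller-sooner
  amount, larger-later amount, delay) triple is enumerated once, and
  pairs are picked whose indifference log10 discount rates sit closest
  to a ladder of evenly spaced target rates on [-4, 0];
* **adaptive** — a grid posterior over the chooser's log discount rate
  is updated after every decision (softmax likelihood at a fixed
  temperature), and the next pair is the one whose indifference rate is
  nearest the current posterior mean.

Blocks where the participant chooses on behalf of a simulated other use
the generative source only, with 50 evenly spaced targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AMOUNT_MAX,
    AMOUNT_MIN,
    DELAY_MAX,
    LL,
    SS,
    ChoicePair,
    MonetaryOption,
    hyperbolic_value,
    kt_choice_prob,
)

__all__ = [
    "BLOCK_LABELS",
    "SELF_BLOCKS",
    "OTHER_BLOCKS",
    "TRIALS_PER_BLOCK",
    "BeliefGrid",
    "SessionSchedule",
    "enumerate_pairs",
    "pair_pool_arrays",
    "make_uniform_targets",
    "generative_pairs",
    "belief_init",
    "belief_update",
    "belief_mean",
    "adaptive_next_pair",
    "build_schedule",
]

BLOCK_LABELS: Tuple[str, ...] = ("Self1", "Other1", "Self2", "Other2", "Self3")
SELF_BLOCKS: Tuple[int, ...] = (1, 3, 5)
OTHER_BLOCKS: Tuple[int, ...] = (2, 4)
TRIALS_PER_BLOCK = 50


@lru_cache(maxsize=1)
def enumerate_pairs() -> Tuple[ChoicePair, ...]:
    """Every admissible pair: integer amounts 1-20 (ss < ll), delays 1-90.

    C(20, 2) x 90 = 17,100 pairs, in deterministic (ss, ll, delay) order.
    """
    pairs = []
    for ss_amt in range(AMOUNT_MIN, AMOUNT_MAX):
        for ll_amt in range(ss_amt + 1, AMOUNT_MAX + 1):
            for delay in range(1, DELAY_MAX + 1):
                pairs.append(
                    ChoicePair(MonetaryOption(ss_amt, 0), MonetaryOption(ll_amt, delay))
                )
    return tuple(pairs)


@lru_cache(maxsize=1)
def pair_pool_arrays():
    """Columnar view of the pair pool for vectorized nearest-rate search."""
    pool = enumerate_pairs()
    ss = np.array([p.ss.amount for p in pool])
    ll = np.array([p.ll.amount for p in pool])
    delay = np.array([p.ll.delay for p in pool])
    logk = np.log10((ll / ss - 1.0) / delay)
    return ss, ll, delay, logk


def _nearest_pair_index(target: float, pool_index=None) -> int:
    """Index of the pool pair whose indifference rate is nearest ``target``.

    Ties broken deterministically: smallest delay, then smallest delayed
    amount, then smallest sooner amount.
    """
    ss, ll, delay, logk = pair_pool_arrays()
    if pool_index is not None:
        pool_index = np.asarray(pool_index)
        ss, ll, delay, logk = (a[pool_index] for a in (ss, ll, delay, logk))
    diff = np.abs(logk - target)
    tie = np.flatnonzero(diff == diff.min())
    best = tie[np.lexsort((ss[tie], ll[tie], delay[tie]))[0]]
    return int(pool_index[best]) if pool_index is not None else int(best)


def make_uniform_targets(n: int, lo: float = -4.0, hi: float = 0.0) -> np.ndarray:
    """``n`` evenly spaced log10 discount-rate targets spanning [lo, hi]."""
    if n < 2:
        raise ValueError("need at least 2 targets")
    return np.linspace(lo, hi, n)


def generative_pairs(
    k_targets: Sequence[float], pool: Sequence[ChoicePair] = None
) -> List[ChoicePair]:
    """For each target rate, the pool pair with the closest indifference rate."""
    all_pairs = enumerate_pairs()
    if pool is None:
        idx = None
    else:
        if len(pool) == 0:
            raise ValueError("empty pair pool")
        lookup = {
            (p.ss.amount, p.ll.amount, p.ll.delay): i for i, p in enumerate(all_pairs)
        }
        idx = [lookup[(p.ss.amount, p.ll.amount, p.ll.delay)] for p in pool]
    return [all_pairs[_nearest_pair_index(t, idx)] for t in np.asarray(k_targets)]


# ---------------------------------------------------------------------------
# Grid posterior over the chooser's log discount rate


@dataclass(frozen=True)
class BeliefGrid:
    """Discretized belief over k = log10(K), used by the adaptive designer
    and by the simulated learner of others' preferences."""

    grid: np.ndarray  # strictly increasing support (log10 rate)
    mass: np.ndarray  # probability weights, sum to 1
    t_fixed: float = 0.3  # log10 softmax temperature in the update likelihood

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-12:
            raise ValueError("mass must be a normalized probability vector")


def belief_init(
    mean: float = -2.0,
    sd: float = 1.0,
    t_fixed: float = 0.3,
    grid_lo: float = -6.0,
    grid_hi: float = 2.0,
    n_points: int = 801,
) -> BeliefGrid:
    """Fresh normal prior over k, discretized on a uniform grid.

    Defaults follow the task's adaptive designer: prior N(-2, 1) and a
    fixed update temperature t = 0.3. The grid spans [-6, 2] so that the
    prior tails and the simulated others' rates (baseline +/- 1, which
    can leave [-4, 0]) stay on-support.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    grid = np.linspace(grid_lo, grid_hi, n_points)
    logmass = -0.5 * ((grid - mean) / sd) ** 2
    mass = np.exp(logmass - logmass.max())
    mass /= mass.sum()
    return BeliefGrid(grid=grid, mass=mass, t_fixed=t_fixed)


def _ll_likelihood(belief: BeliefGrid, pair: ChoicePair) -> np.ndarray:
    """P(choose LL | k) at every grid point, softmax at ``t_fixed``."""
    K = 10.0**belief.grid
    v_ll = hyperbolic_value((pair.ll.amount, pair.ll.delay), K)
    return kt_choice_prob(v_ll, pair.ss.amount, belief.t_fixed)


def belief_update(belief: BeliefGrid, pair: ChoicePair, choice: str) -> BeliefGrid:
    """Bayes update of the belief grid after observing one choice."""
    p_ll = _ll_likelihood(belief, pair)
    like = p_ll if choice == LL else 1.0 - p_ll
    post = belief.mass * like
    total = post.sum()
    if not total > 0:
        raise RuntimeError("belief update produced zero total mass")
    return replace(belief, mass=post / total)


def belief_mean(belief: BeliefGrid) -> float:
    """Posterior-mean log10 discount rate."""
    return float(np.dot(belief.grid, belief.mass))


def adaptive_next_pair(
    belief: BeliefGrid, pool: Sequence[ChoicePair] = None
) -> ChoicePair:
    """Pair probing the current indifference-point estimate.

    Returns the pool pair whose indifference rate is nearest the belief's
    posterior mean; deterministic given the belief (tie-break: smallest
    delay, then smallest delayed amount).
    """
    return generative_pairs([belief_mean(belief)], pool)[0]


# ---------------------------------------------------------------------------
# Session schedule


@dataclass(frozen=True)
class SessionSchedule:
    """A 5-block, 250-trial session layout.

    One row per trial slot with its design tag ('generative' or
    'adaptive') and, for generative slots, the target indifference rate;
    adaptive slots are filled at run time from the live belief.
    """

    frame: pd.DataFrame  # block, block_label, trial, design_tag, target
    other_order: str  # impulsive_first | patient_first

    def __post_init__(self) -> None:
        if self.other_order not in ("impulsive_first", "patient_first"):
            raise ValueError("other_order must be impulsive_first or patient_first")
        if len(self.frame) != len(BLOCK_LABELS) * TRIALS_PER_BLOCK:
            raise ValueError("schedule must hold 5 blocks x 50 trials")


def build_schedule(other_order: str = "impulsive_first", seed: int = 0) -> SessionSchedule:
    """Assemble the default session: Self1, Other1, Self2, Other2, Self3.

    Self blocks interleave 25 generative trials (targets evenly spaced on
    [-4, 0], shuffled) with 25 adaptive trials, in seeded-random order.
    Other blocks are fully generative with 50 evenly spaced targets in
    shuffled order. A self-paced break is implied after trial 25 of every
    block (it does not affect the data layout).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for block, label in enumerate(BLOCK_LABELS, start=1):
        if block in SELF_BLOCKS:
            tags = np.array(["generative"] * 25 + ["adaptive"] * 25)
            rng.shuffle(tags)
            targets = rng.permutation(make_uniform_targets(25))
            it = iter(targets)
            target_col = [next(it) if tag == "generative" else np.nan for tag in tags]
        else:
            tags = np.array(["generative"] * TRIALS_PER_BLOCK)
            target_col = list(rng.permutation(make_uniform_targets(50)))
        for trial in range(1, TRIALS_PER_BLOCK + 1):
            rows.append(
                {
                    "block": block,
                    "block_label": label,
                    "trial": trial,
                    "design_tag": tags[trial - 1],
                    "target": target_col[trial - 1],
                }
            )
    return SessionSchedule(frame=pd.DataFrame(rows), other_order=other_order)
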