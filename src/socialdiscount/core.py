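"""Valuation and choice rules for smaller-sooner / larger-later decisions.

Two accounts of a discounter are used throughout the package:

* the **KT model** — a point preference: a hyperbolic discount rate
  ``K`` (analysed on the log scale, ``k = log10 K``) plus a softmax
  inverse temperature ``T`` (``t = log10 T``) that converts the value
  difference of the two options into a choice probability;
* the **KU model** — a preference *distribution*: on every trial the
  agent draws ``k ~ N(km, ku^2)`` and picks the delayed option whenever
  the drawn rate is below the pair's indifference rate, so the choice
  probability is a normal CDF evaluated at that indifference rate.

All functions accept numpy arrays in place of scalars and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "SS",
    "LL",
    "AMOUNT_MIN",
    "AMOUNT_MAX",
    "DELAY_MIN",
    "DELAY_MAX",
    "MonetaryOption",
    "ChoicePair",
    "KTParams",
    "KUParams",
    "Decision",
    "hyperbolic_value",
    "kt_choice_prob",
    "ku_choice_prob",
    "indifference_logk",
]

#: Choice labels used across the package and in trial-log files.
SS = "SS"
LL = "LL"

# Task currency/delay ranges: rewards are whole pounds between 1 and 20,
# delays whole days; the delayed option pays after 1-90 days, the sooner
# option pays today (delay 0).
AMOUNT_MIN, AMOUNT_MAX = 1, 20
DELAY_MIN, DELAY_MAX = 0, 90


@dataclass(frozen=True)
class MonetaryOption:
    """A monetary reward of ``amount`` pounds delivered after ``delay`` days."""

    amount: int
    delay: int

    def __post_init__(self) -> None:
        if not (AMOUNT_MIN <= self.amount <= AMOUNT_MAX):
            raise ValueError(
                f"amount must be in [{AMOUNT_MIN}, {AMOUNT_MAX}] pounds, got {self.amount}"
            )
        if not (DELAY_MIN <= self.delay <= DELAY_MAX):
            raise ValueError(
                f"delay must be in [{DELAY_MIN}, {DELAY_MAX}] days, got {self.delay}"
            )


@dataclass(frozen=True)
class ChoicePair:
    """A smaller-sooner option (paid today) vs a larger-later option.

    The pair's ``indifference_logk`` is the log10 discount rate at which
    the two options have equal subjective value under hyperbolic
    discounting; an agent discounting more slowly than that rate prefers
    the delayed option.
    """

    ss: MonetaryOption
    ll: MonetaryOption

    def __post_init__(self) -> None:
        if self.ss.delay != 0:
            raise ValueError("smaller-sooner option must be delivered today (delay 0)")
        if self.ll.delay < 1:
            raise ValueError("larger-later option must have delay >= 1 day")
        if self.ll.amount <= self.ss.amount:
            raise ValueError(
                "larger-later amount must exceed smaller-sooner amount "
                "(indifference rate undefined otherwise)"
            )

    @property
    def indifference_logk(self) -> float:
        return float(
            np.log10((self.ll.amount / self.ss.amount - 1.0) / self.ll.delay)
        )


@dataclass(frozen=True)
class KTParams:
    """Point-preference discounter: k = log10(K), t = log10(T)."""

    k: float
    t: float

    def __post_init__(self) -> None:
        if not (-4.0 <= self.k <= 0.0):
            raise ValueError(f"k must lie in [-4, 0], got {self.k}")
        if not (-1.0 <= self.t <= 1.0):
            raise ValueError(f"t must lie in [-1, 1], got {self.t}")

    @property
    def K(self) -> float:
        return 10.0**self.k

    @property
    def T(self) -> float:
        return 10.0**self.t


@dataclass(frozen=True)
class KUParams:
    """Distribution-preference discounter: per-trial k ~ N(km, ku^2).

    ``km`` indexes temporal impulsivity (higher = steeper discounting),
    ``ku`` preference uncertainty. ``km`` must be negative and ``ku``
    positive, matching the constraints used in model fitting.
    """

    km: float
    ku: float

    def __post_init__(self) -> None:
        if not self.km < 0:
            raise ValueError(f"km must be negative, got {self.km}")
        if not self.ku > 0:
            raise ValueError(f"ku must be positive, got {self.ku}")


@dataclass
class Decision:
    """One trial's outcome in a session trial log."""

    pair: ChoicePair
    choice: str
    block: int
    trial: int
    agent: str = "self"  # self | other_A | other_B
    feedback_correct: Optional[bool] = field(default=None)

    def __post_init__(self) -> None:
        if self.choice not in (SS, LL):
            raise ValueError(f"choice must be {SS!r} or {LL!r}, got {self.choice!r}")
        if not (1 <= self.block <= 5):
            raise ValueError("block must be 1-5")
        if not (1 <= self.trial <= 50):
            raise ValueError("trial must be 1-50")
        is_self_block = self.block in (1, 3, 5)
        if is_self_block != (self.agent == "self"):
            raise ValueError("agent must be 'self' exactly in blocks 1, 3 and 5")
        if (self.feedback_correct is not None) != (self.block in (2, 4)):
            raise ValueError("feedback_correct present exactly in blocks 2 and 4")


def hyperbolic_value(option, K):
    """Subjective value (pounds) of ``option`` under hyperbolic discounting.

    V = amount / (1 + K * delay); an immediate reward keeps its face value.
    ``option`` may be a :class:`MonetaryOption` or an ``(amount, delay)``
    pair of scalars/arrays; ``K`` is the per-day discount rate (>= 0).
    """
    if isinstance(option, MonetaryOption):
        amount, delay = option.amount, option.delay
    else:
        amount, delay = option
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("discount rate K must be non-negative")
    out = amount / (1.0 + K * delay)
    return float(out) if np.isscalar(amount) and out.ndim == 0 else out


def kt_choice_prob(v_ll, v_ss, t):
    """Softmax probability of choosing the delayed option.

    P(LL) = logistic(T * (v_ll - v_ss)) with T = 10**t. Computed via the
    log-safe logistic, so extreme temperatures do not under/overflow.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    T = 10.0**t
    out = expit(T * (np.asarray(v_ll, dtype=float) - np.asarray(v_ss, dtype=float)))
    return float(out) if out.ndim == 0 else out


def indifference_logk(pair=None, *, ss_amount=None, ll_amount=None, delay=None):
    """log10 discount rate at which the two options are equally valued.

    Solves amount_ss = amount_ll / (1 + K * delay) for K and returns
    log10(K) = log10((ll/ss - 1) / delay). Accepts either a
    :class:`ChoicePair` or the three raw fields (arrays broadcast).
    """
    if pair is not None:
        return pair.indifference_logk
    ss_amount = np.asarray(ss_amount, dtype=float)
    ll_amount = np.asarray(ll_amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(ll_amount <= ss_amount):
        raise ValueError("indifference rate undefined unless ll_amount > ss_amount")
    if np.any(delay < 1):
        raise ValueError("delayed option needs delay >= 1 day")
    out = np.log10((ll_amount / ss_amount - 1.0) / delay)
    return float(out) if out.ndim == 0 else out


def ku_choice_prob(pair, params: KUParams = None, *, km=None, ku=None, threshold=None):
    """Probability that a KU discounter picks the delayed option.

    The agent samples k ~ N(km, ku^2) and chooses the delayed option iff
    the sampled rate is below the pair's indifference rate, hence
    P(LL) = Phi((indifference_logk - km) / ku).

    Either pass ``(pair, params)`` or the raw ``threshold`` (= the pair's
    indifference log10 rate), ``km`` and ``ku`` as arrays.
    """
    if params is not None:
        km, ku = params.km, params.ku
    if threshold is None:
        threshold = (
            pair.indifference_logk if isinstance(pair, ChoicePair) else np.asarray(pair)
        )
    km = np.asarray(km, dtype=float)
    ku = np.asarray(ku, dtype=float)
    if np.any(ku <= 0):
        raise ValueError("ku must be positive")
    out = ndtr((np.asarray(threshold, dtype=float) - km) / ku)
    return float(out) if out.ndim == 0 else out
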