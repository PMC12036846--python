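"""Simulated agents: the two artificial "other" players, stochastic
KT/KU choosers, and the learner that infers an other's preference from
trial-and-error feedback.

The two others are built from the participant's own baseline log
discount rate estimated in the first self block: one discounts one
log10 unit faster (*more impulsive*), one a unit slower (*more
patient*). Their choices are hyperbolic-discounter softmax draws at
temperature t = 1 (log10 scale, i.e. T = 10), so feedback is noisy; the
"correct" choice on a trial is the one with the greater discounted
value at the other's true rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binomtest

from .core import LL, SS, ChoicePair, KTParams, KUParams, hyperbolic_value, ku_choice_prob
from .design import BeliefGrid, belief_init, belief_mean, belief_update

__all__ = [
    "OtherSpec",
    "LearnerState",
    "OtherBlockResult",
    "make_others",
    "label_other",
    "simulate_choice_kt",
    "simulate_choice_ku",
    "correct_choice",
    "simulate_other_block",
    "accuracy_binomial_test",
]


@dataclass(frozen=True)
class OtherSpec:
    """One simulated other player.

    ``k_other`` is the player's true log10 discount rate (baseline +/- 1,
    never clipped, so it may leave [-4, 0]); ``design_label`` records the
    intended direction. ``t_sim`` is the softmax temperature of the
    player's choices, on the log10 scale by default (t_sim = 1 -> T = 10).
    """

    k_other: float
    design_label: str  # more_impulsive | more_patient
    t_sim: float = 1.0
    t_is_log10: bool = True

    @property
    def T(self) -> float:
        return 10.0**self.t_sim if self.t_is_log10 else self.t_sim


def make_others(
    baseline_k: float, t_sim: float = 1.0, t_is_log10: bool = True
) -> Tuple[OtherSpec, OtherSpec]:
    """The (more impulsive, more patient) pair at baseline_k +/- 1."""
    if not np.isfinite(baseline_k):
        raise ValueError("baseline_k must be finite")
    imp = OtherSpec(baseline_k + 1.0, "more_impulsive", t_sim, t_is_log10)
    pat = OtherSpec(baseline_k - 1.0, "more_patient", t_sim, t_is_log10)
    return imp, pat


def label_other(k_other: float, reference_km: float) -> str:
    """Analysis label for an other relative to a fitted baseline km.

    Assigned by the sign of (k_other - reference_km), so it can disagree
    with the design intent when the fitted baseline sits more than one
    log-unit from the design baseline — in which case both others end up
    on the same side.
    """
    return "more_impulsive" if k_other >= reference_km else "more_patient"


def _p_ll_kt(pair: ChoicePair, k: float, T: float) -> float:
    v_ll = hyperbolic_value((pair.ll.amount, pair.ll.delay), 10.0**k)
    # kt_choice_prob expects t = log10(T); use T directly via the logistic
    from scipy.special import expit

    return float(expit(T * (v_ll - pair.ss.amount)))


def simulate_choice_kt(pair: ChoicePair, params, rng: np.random.Generator) -> str:
    """One Bernoulli softmax choice of a point-preference discounter.

    ``params`` may be a :class:`KTParams`, an :class:`OtherSpec`, or a raw
    ``(k, t_log10)`` tuple (raw tuples are not range-checked, which the
    simulated others need since their rates may leave [-4, 0]).
    """
    if isinstance(params, OtherSpec):
        k, T = params.k_other, params.T
    elif isinstance(params, KTParams):
        k, T = params.k, params.T
    else:
        k, t = params
        T = 10.0**t
    return LL if rng.random() < _p_ll_kt(pair, k, T) else SS


def simulate_choice_ku(pair: ChoicePair, params: KUParams, rng: np.random.Generator) -> str:
    """One choice of a distribution-preference discounter (normal-CDF rule)."""
    return LL if rng.random() < ku_choice_prob(pair, params) else SS


def correct_choice(pair: ChoicePair, k_other: float) -> str:
    """The option with the greater hyperbolic value at rate ``k_other``.

    LL iff k_other is below the pair's indifference rate; exact ties are
    labelled LL for determinism (a measure-zero case).
    """
    return LL if k_other <= pair.indifference_logk else SS


@dataclass
class LearnerState:
    """Belief over an other's log discount rate plus its trial history."""

    belief: BeliefGrid
    history: List[dict] = field(default_factory=list)


@dataclass
class OtherBlockResult:
    """Outcome of one simulated 50-trial other-learning block."""

    pairs: Sequence[ChoicePair]
    learner_choices: List[str]
    other_choices: List[str]
    correct_choices: List[str]
    feedback_correct: List[bool]  # learner choice matched the other's shown choice
    accuracy: float  # fraction matching the value-maximizing choice
    learner: LearnerState


def simulate_other_block(
    other: OtherSpec,
    pairs: Sequence[ChoicePair],
    rng: np.random.Generator,
    learner: Optional[LearnerState] = None,
    prior_mean: float = -2.0,
    prior_sd: float = 1.0,
    decision_t: Optional[float] = -0.2,
) -> OtherBlockResult:
    """Simulate a learner choosing on the other's behalf with feedback.

    Each trial the learner predicts the other's choice from its current
    posterior-mean rate estimate — deterministically if ``decision_t`` is
    None, otherwise through its own softmax at log10 temperature
    ``decision_t`` — then sees the other's (stochastic) choice as
    feedback and updates its belief by Bayes' rule on the grid.

    Accuracy is scored against the deterministic value-maximizing choice
    at the other's true rate, matching how learning performance is
    evaluated, while the feedback shown is the noisy simulated choice.
    """
    if learner is None:
        learner = LearnerState(belief=belief_init(mean=prior_mean, sd=prior_sd))
    learner_choices, other_choices, corrects, fb = [], [], [], []
    for pair in pairs:
        k_hat = belief_mean(learner.belief)
        if decision_t is None:
            chosen = correct_choice(pair, k_hat)
        else:
            chosen = simulate_choice_kt(pair, (k_hat, decision_t), rng)
        shown = simulate_choice_kt(pair, other, rng)
        best = correct_choice(pair, other.k_other)
        learner.belief = belief_update(learner.belief, pair, shown)
        learner.history.append(
            {"pair": pair, "learner": chosen, "other": shown, "correct": best}
        )
        learner_choices.append(chosen)
        other_choices.append(shown)
        corrects.append(best)
        fb.append(chosen == shown)
    acc = float(np.mean([c == b for c, b in zip(learner_choices, corrects)]))
    return OtherBlockResult(
        pairs=pairs,
        learner_choices=learner_choices,
        other_choices=other_choices,
        correct_choices=corrects,
        feedback_correct=fb,
        accuracy=acc,
        learner=learner,
    )


def accuracy_binomial_test(n_correct: int, n_trials: int) -> float:
    """Right-tailed exact binomial p-value against the 50% chance level."""
    if not (0 <= n_correct <= n_trials):
        raise ValueError("need 0 <= n_correct <= n_trials")
    return float(binomtest(n_correct, n_trials, 0.5, alternative="greater").pvalue)
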