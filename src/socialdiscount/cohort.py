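"""Synthetic study cohorts with the full session structure.

Each synthetic participant is a KU chooser. The generator reproduces
the complete 250-trial session: a mixed generative/adaptive Self1
block, a KT grid fit of that block to set the baseline rate, two
simulated others at baseline +/- 1, feedback-driven other-learning
blocks, and — the generative stand-in for social contagion — a
fractional shift of the participant's km toward the just-learned
other's rate before each subsequent Self block. The true parameters of
every stage are emitted alongside the trial log so that fitting,
divergence and recovery code can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .agents import make_others, simulate_choice_ku, simulate_other_block
from .core import KUParams
from .design import (
    BLOCK_LABELS,
    OTHER_BLOCKS,
    adaptive_next_pair,
    belief_init,
    belief_update,
    build_schedule,
    generative_pairs,
)
from .fitting import KTGridModel

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort", "default_paper_like_spec"]

# Subject-level parameter draws are rejection-sampled into the task's
# measurable preference range (pairs span indifference rates of roughly
# [-3.2, 1.3]; design targets span [-4, 0]).
KM_RANGE = (-4.0, -0.05)
KU_RANGE = (0.05, 2.0)


@dataclass(frozen=True)
class GroupSpec:
    """Population parameters for one participant group."""

    label: str
    n_subjects: int
    km_mean: float
    km_sd: float
    ku_mean: float
    ku_sd: float
    susceptibility_impulsive: float = 0.3
    susceptibility_patient: float = 0.3
    learner_noise: Optional[float] = -0.2  # log10 softmax T; None = noise-free

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.km_sd <= 0 or self.ku_sd <= 0:
            raise ValueError("population SDs must be positive")
        for s in (self.susceptibility_impulsive, self.susceptibility_patient):
            if not (0.0 <= s <= 1.0):
                raise ValueError("susceptibilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: Tuple[GroupSpec, ...]
    seed: int = 0
    learner_prior_sd: float = 1.0
    shift_ku: bool = False  # ku is held fixed across blocks by default


def default_paper_like_spec(seed: int = 0) -> CohortSpec:
    """Three groups (71 controls, 33 mPFC-analogue, 17 lesion-control
    analogue) with directional effects: the mPFC analogue discounts more
    steeply at baseline and is more susceptible to the impulsive other;
    the lesion-control analogue has higher preference uncertainty.
    Magnitudes are free choices of the generator, not fitted values.
    """
    return CohortSpec(
        groups=(
            GroupSpec("HC", 71, -2.0, 0.6, 0.5, 0.15, 0.3, 0.3),
            GroupSpec("mPFC", 33, -1.5, 0.6, 0.5, 0.15, 0.5, 0.3),
            GroupSpec("LC", 17, -2.0, 0.6, 0.8, 0.2, 0.3, 0.3),
        ),
        seed=seed,
    )


def _draw_truncated(rng, mean, sd, lo, hi):
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("rejection sampling failed; population far outside range")


def _run_self_block(block, label, schedule, belief, km, ku, rng, rows, subject_id, group):
    params = KUParams(km=km, ku=ku)
    sub = schedule.frame[schedule.frame["block"] == block]
    for r in sub.itertuples():
        if r.design_tag == "generative":
            pair = generative_pairs([r.target])[0]
        else:
            pair = adaptive_next_pair(belief)
        choice = simulate_choice_ku(pair, params, rng)
        belief = belief_update(belief, pair, choice)
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "block": block,
                "block_label": label,
                "trial": r.trial,
                "design_tag": r.design_tag,
                "agent": "self",
                "ss_amount": pair.ss.amount,
                "ll_amount": pair.ll.amount,
                "delay_days": pair.ll.delay,
                "choice": choice,
                "feedback_correct": pd.NA,
            }
        )
    return belief


def generate_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject's full session.

    Returns ``(trials, truth)``: the tidy 250-row-per-subject trial log,
    and the ground-truth table (true parameters per stage, the others'
    rates, realized learning accuracies).
    """
    root = np.random.SeedSequence(spec.seed)
    rows: List[dict] = []
    truth_rows: List[dict] = []
    subject_counter = 0
    group_seeds = root.spawn(len(spec.groups))
    for gspec, gseed in zip(spec.groups, group_seeds):
        subj_seeds = gseed.spawn(gspec.n_subjects)
        for j, sseq in enumerate(subj_seeds):
            rng = np.random.default_rng(sseq)
            subject_id = f"{gspec.label}_{j + 1:03d}"
            other_order = (
                "impulsive_first" if subject_counter % 2 == 0 else "patient_first"
            )
            schedule = build_schedule(
                other_order=other_order, seed=int(rng.integers(2**31 - 1))
            )
            km0 = _draw_truncated(rng, gspec.km_mean, gspec.km_sd, *KM_RANGE)
            ku0 = _draw_truncated(rng, gspec.ku_mean, gspec.ku_sd, *KU_RANGE)
            km_cur, ku_cur = km0, ku0
            km_by_block = {}

            # Self1 + designer belief (persists across the Self blocks)
            belief = belief_init()
            km_by_block[1] = km_cur
            belief = _run_self_block(
                1, "Self1", schedule, belief, km_cur, ku_cur, rng, rows,
                subject_id, gspec.label,
            )

            self1 = pd.DataFrame([r for r in rows if r["subject_id"] == subject_id])
            baseline_k = KTGridModel().fit(self1).k_mean_
            imp, pat = make_others(baseline_k)
            if other_order == "impulsive_first":
                others_in_order = [imp, pat]
            else:
                others_in_order = [pat, imp]

            accuracies = {}
            for idx, block in enumerate(OTHER_BLOCKS):
                other = others_in_order[idx]
                sub = schedule.frame[schedule.frame["block"] == block]
                pairs = generative_pairs(sub["target"].to_numpy())
                res = simulate_other_block(
                    other,
                    pairs,
                    rng,
                    prior_mean=baseline_k,
                    prior_sd=spec.learner_prior_sd,
                    decision_t=gspec.learner_noise,
                )
                accuracies[block] = res.accuracy
                agent = "other_A" if block == 2 else "other_B"
                for t, (pair, choice, fb) in enumerate(
                    zip(pairs, res.learner_choices, res.feedback_correct), start=1
                ):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "group": gspec.label,
                            "block": block,
                            "block_label": BLOCK_LABELS[block - 1],
                            "trial": t,
                            "design_tag": "generative",
                            "agent": agent,
                            "ss_amount": pair.ss.amount,
                            "ll_amount": pair.ll.amount,
                            "delay_days": pair.ll.delay,
                            "choice": choice,
                            "feedback_correct": fb,
                        }
                    )

                # social-influence injection: fractional km shift toward
                # the just-learned other's rate
                s = (
                    gspec.susceptibility_impulsive
                    if other.design_label == "more_impulsive"
                    else gspec.susceptibility_patient
                )
                km_cur = min(km_cur + s * (other.k_other - km_cur), -1e-2)
                next_self = block + 1
                km_by_block[next_self] = km_cur
                belief = _run_self_block(
                    next_self,
                    BLOCK_LABELS[next_self - 1],
                    schedule,
                    belief,
                    km_cur,
                    ku_cur,
                    rng,
                    rows,
                    subject_id,
                    gspec.label,
                )

            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": gspec.label,
                    "other_order": other_order,
                    "km_true": km0,
                    "ku_true": ku0,
                    "km_self2_true": km_by_block[3],
                    "km_self3_true": km_by_block[5],
                    "baseline_kt_k": baseline_k,
                    "k_other_impulsive": imp.k_other,
                    "k_other_patient": pat.k_other,
                    "k_other_block2": others_in_order[0].k_other,
                    "k_other_block4": others_in_order[1].k_other,
                    "accuracy_block2": accuracies[2],
                    "accuracy_block4": accuracies[4],
                    "susceptibility_impulsive": gspec.susceptibility_impulsive,
                    "susceptibility_patient": gspec.susceptibility_patient,
                }
            )
            subject_counter += 1

    trials = pd.DataFrame(rows)
    trials["rng_stream_id"] = trials["subject_id"]
    truth = pd.DataFrame(truth_rows)
    return trials, truth
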