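# Methods

This note documents the models, algorithms and design decisions in
`socialdiscount`, in the spirit of a model-description appendix.

## Choice models

**Valuation.** A delayed reward of `M` pounds at `D` days is valued
hyperbolically, `V = M/(1 + K·D)`, with the per-day discount rate `K`
analysed as `k = log10 K`. An immediate reward keeps its face value.
For a pair (smaller-sooner `M_SS` today vs larger-later `M_LL` at `D`),
the *indifference rate* `x = log10[(M_LL/M_SS − 1)/D]` is the rate at
which the two values are equal; agents with `k < x` prefer the delayed
option. Amounts are integer pounds in [1, 20] and delays integer days
in [0, 90] (0 only for the sooner option), which makes the pair space
finite: C(20,2) × 90 = 17,100 admissible pairs whose indifference rates
span ≈ [−3.23, +1.28].

**KT (preference–temperature).** A point preference `k` plus a softmax
on the value difference, `P(LL) = logistic(T·(V_LL − V_SS))` with
`T = 10^t`. The task design constrains `k ∈ [−4, 0]` and `t ∈ [−1, 1]`.
The KT model is used where a point estimate of the rate is needed: the
adaptive designer's update likelihood (with `t` fixed at 0.3), the
Self1 baseline fit, and the simulated partners.

**KU (preference–uncertainty).** The discount rate is a distribution:
each trial's `k` is drawn from `N(km, ku²)`, so
`P(LL) = Φ((x − km)/ku)`. `km < 0` and `ku > 0` are enforced
throughout. This is the model fitted to all trial data.

## Task design

A session is five 50-trial blocks (Self1, Other1, Self2, Other2,
Self3). Self blocks interleave, in seeded-random order, 25 *generative*
trials — pairs matched to 25 evenly spaced target rates on [−4, 0] —
and 25 *adaptive* trials. Other blocks use 50 generative targets on
[−4, 0]. Pair lookup minimizes |indifference − target| over the full
pool, with deterministic tie-breaking (smallest delay, then smallest
delayed amount, then smallest sooner amount); a sorted-array search
implements it exactly and is oracle-tested against the brute-force
scan.

The adaptive designer maintains a grid belief over `k`: 801 points
uniform on [−6, 2] (covering the prior's tails and partner rates
outside [−4, 0]), initialized to N(−2, 1), updated after every decision
by Bayes' rule with the KT likelihood at `t = 0.3`, and probed at the
posterior mean. The belief persists across the three Self blocks of a
session (the designer tracks one participant throughout); other-block
learning uses its own fresh belief per partner. Repeated pairs are
allowed.

## Simulated partners and the learner

Each participant's Self1 choices are fit with the KT model by exact
grid integration (81 × 41 uniform grid over `[−4, 0] × [−1, 1]`); the
posterior-mean `k` is the baseline. The two partners sit at baseline
± 1 (no clipping, so rates may leave [−4, 0]) and answer through a
softmax at `t = 1` on the log10 scale (T = 10); a flag switches to
T = 1 for the alternative reading of that temperature.

The learner that generates other-block behavior predicts the partner's
choice from its current posterior-mean rate estimate through its own
softmax, then updates its grid belief on the partner's *shown*
(stochastic) choice. Accuracy is scored against the value-maximizing
choice at the partner's true rate, with exact indifference ties
labelled LL for determinism. The learner's decision temperature
defaults to `t = −0.2`, calibrated so that simulated cohorts reproduce
the 78–85% mean learning-accuracy band observed empirically in this
paradigm (≈ 0.85 at default settings, with ≈ 98% of subjects above the
50% chance level at p < 0.001 by right-tailed exact binomial test).
Analysis labels (*more impulsive* / *more patient*) are assigned
relative to the fitted baseline `km`, so both partners of a subject can
receive the same label; such subjects contribute no rows for the
missing label in the influence table and are flagged.

## Hierarchical Bayesian fitting

Each block × group is fit independently with identical
weakly-informative priors (priors reset per block). Subject-level
parameters follow truncated group-level normals — `km_i ~ N(μ_km,
σ_km²)` truncated to (−∞, 0), `ku_i ~ N(μ_ku, σ_ku²)` truncated to
(0, ∞) — with `μ ~ N(0, 3)` and `σ ~ half-Cauchy(0, 2)`. The truncation
normalizers are included in the group-parameter conditionals, so the
hierarchy is a proper truncated-normal model; a consequence used as a
correctness test is that prior-only sampling returns exactly the
hyperpriors. We chose direct truncation over an unconstrained-latent
transform (`km = −exp(z)`): the transform's main benefit is HMC
geometry, which is irrelevant to our sampler, and truncation keeps the
subject-level parameters on their natural scale.

**Sampler.** Inference uses adaptive Metropolis-within-Gibbs,
vectorized over chains and subjects. Each iteration proposes all
subject-level `(km_i, ku_i)` pairs jointly (their full conditionals are
independent across subjects given the group parameters, so the
accept/reject step vectorizes), then updates each group-level parameter
with a scalar random walk (log-scale walk with Jacobian for the SDs).
Proposal scales adapt per subject and per group parameter during warmup
only (stochastic approximation toward 30% / 44% acceptance), keeping
the post-warmup chain Markovian. Start values are overdispersed around
crude per-subject quantile estimates. The default schedule is 4 chains
× 2,000 warmup + 2,000 retained iterations (8,000 draws); scaled-down
schedules (4 × 500/500 or less) are used in the test-time harnesses.
Convergence is summarized by split-chain R̂ for every parameter
(constant chains defined as R̂ = 1), cross-checked against an
independent implementation in the tests; fits warn (not fail) above
1.05, and ≤ 1.01 is considered clean. Likelihoods are computed with
`log Φ` via complementary error functions, so extreme `ku` or `t`
values do not underflow.

## Influence statistic

The preference shift after an exposure is `D_KL(P‖Q)` between normals,
with the base-10 logarithm as this analysis defines it:
`[ln(σ_Q/σ_P) + (σ_P² + (μ_P − μ_Q)²)/(2σ_Q²) − ½]/ln 10`, where `P` is
the post-exposure KU distribution (posterior-mean parameters of the
Self block following the exposure) and `Q` the Self1 baseline. The sign
follows `sign[(km_other − km_self1)/(km_after − km_self1)]` — positive
when the shift is toward the partner. Both exposures are anchored at
Self1: both partners are constructed from the Self1 baseline, so the
Self1 anchor keeps numerator and denominator on the same reference
(the alternative "successive blocks" reading would compare Self3
against Self2 for the second exposure). When `|km_after − km_self1| <
1e−8` the sign is set to 0 with a warning (a measure-zero degeneracy
needing a deterministic rule). A sample-based variant of the divergence
(computed from MCMC draws rather than posterior-mean normals) is
deliberately not the default: the closed form on posterior-mean
parameters is the reading adopted, and it is what the tests validate.

## Parameter recovery

Per repetition: group-level parameters are drawn from the fitting
priors, 120 subjects are drawn from the implied truncated normals, each
makes 50 choices on the fixed generative ladder of 50 evenly spaced
targets (one design shared by all subjects and repetitions), the
hierarchical model is refit, and true vs posterior-mean subject
parameters are compared by Spearman's ρ, Fisher-z-averaged across
repetitions (20 at full scale; 3 in the quick harness, with the MCMC
schedule reduced to 4 × 500/500).

**Measurable-regime restriction.** Raw draws from N(0, 3) × half-
Cauchy(0, 2) frequently place entire cohorts outside what the task can
measure — below the pair pool's indifference floor (≈ −3.23, where
every probe is answered the same way), beyond `ku ≈ 1` (where the whole
ladder approaches coin flips), or in clusters narrower than the probe
spacing. A rank-correlation recovery study on such populations measures
the task's range, not the model's identifiability. Group-level means
are therefore rejection-sampled into the task's measurable box (`km ∈
[−3.2, −0.05]`, `ku ∈ (0.05, 1]` — one log-unit, the uncertainty scale
the adaptive designer itself assumes), group SDs into [0.2, 1], and
subject draws into the same box (which also enforces the sign
constraints). The fit itself keeps only the sign constraints.

**Known limitation.** Within this regime, `km` rank recovery is
reliably high (Fisher-z ≈ 0.91–0.97 across seeds), but `ku` recovery is
information-limited at 50 trials: the per-subject posterior uncertainty
of `ku` (≈ 0.1–0.15) is not small relative to typical population
spreads, capping Fisher-z `ku` at ≈ 0.77–0.86 depending on the drawn
populations — high-mean-`ku` or boundary-hugging populations recover
worst. More trials or narrower populations would be needed to push
`ku` rank recovery above 0.87 uniformly; we report the honest value
rather than restrict the populations further.

## Posterior predictive checks

For a fitted block, every trial is replayed with choices simulated from
the subject-level posterior draws — one simulated decision per retained
draw (8,000 at the default schedule) — and scored with the same
accuracy statistic as real data (fraction matching the
value-maximizing choice at the partner's rate). Cell summaries
(group × partner label) report the predictive mean and central 95%
interval of the group-mean accuracy across draws. Requesting more
predictive draws than retained posterior draws is an error unless
resampling is explicitly enabled.

## Synthetic cohorts

The generator emulates the full study: per subject, draw `(km, ku)`
from the group's population (rejection-sampled into `km ∈ [−4, −0.05]`,
`ku ∈ [0.05, 2]`), run Self1 with the mixed design, fit the KT
baseline, build partners at ± 1, simulate the two learning blocks, and
— the generative stand-in for contagion, which the analysis measures
but the study does not mechanistically model — shift `km` fractionally
toward the just-learned partner's rate (`km ← km + s·(k_other − km)`,
capped below 0) before each subsequent Self block; `ku` is held fixed
across blocks by default (a flag enables `ku` shifts). Partner order
alternates by subject index. The default three-group cohort has sizes
71/33/17 with directional effects only — the second group discounts
more steeply at baseline and is more susceptible to the impulsive
partner, the third has higher preference uncertainty; magnitudes
(`km` means −2.0/−1.5/−2.0, SD 0.6; `ku` means 0.5/0.5/0.8;
susceptibilities 0.3 vs 0.5) are free choices of the generator.

What the generator does *not* emulate: questionnaire scores, lesions or
any neural data, session-order or fatigue effects, non-stationary `ku`,
and any richer contagion mechanism than the linear `km` shift. Passing
tests therefore show that the pipeline recovers what this generative
family injects — not that real cohorts satisfy the model.

## Numerics, determinism and problem sizes

All randomness flows from explicit seeds through named
`numpy.random.SeedSequence` substreams (cohorts are byte-identical
given a seed; recovery reports are bit-for-bit reproducible). Belief
grids renormalize after every update and reject zero-mass posteriors.
Nearest-pair ties, sign-zero divergences and `correct_choice` ties all
have documented deterministic rules. The test suite runs its heavy
checks at reduced problem sizes chosen as representative: recovery at
120 × 50 × 3 with 4 × 500/500 chains, sign-recovery cohorts of 30
subjects, the directional end-to-end check at the full 121-subject
default cohort across 10 seeds with 4 × 300/300 chains, all well under
typical CI budgets.
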