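# Methods

`arbrl` implements a two-stage Markov decision task with blockwise
manipulations of state-transition uncertainty and state-space complexity,
the computational agents that solve it (a model-based FORWARD learner, a
model-free SARSA learner, and a dynamic arbitrator that allocates control
between them), a 117-variant hypothesis space over how complexity enters the
arbitration, and the machinery to fit those variants to choice data and
compare them. This note records the model, the defaults, and the design
choices that were genuinely open.

## The task

One trial: token exchange rates for (red, blue, silver) are drawn i.i.d.
from U(1,10) and shown; the agent makes a binary choice (L1/R1) in the start
state, transitions to one of two second-stage states, chooses again (2
options under low complexity, 4 under high), and lands in one of eight
outcome states, each labelled red/blue/silver/none. Token-bearing outcomes
pay the token's current value with probability 0.8. Transition probabilities
are (0.9, 0.1) in low-uncertainty blocks (3–5 trials) and (0.5, 0.5) in
high-uncertainty blocks (5–7 trials); complexity also varies by block.
Sessions target 80 trials (5 sessions per subject by default); U(1,10) is
read as the discrete uniform on whole cents, with a continuous option.

Choices made once per design:

* **Block draws.** Uncertainty is drawn per block with P(low) = 0.6, not
  0.5: low-uncertainty blocks average 4 trials and high-uncertainty 6, so
  0.6/0.4 equalises the *trial-level* exposure of the four condition cells
  (each 25 % of trials in expectation). Complexity is drawn at 0.5.
* **Token map.** The default outcome labelling is asymmetric — silver occurs
  only in the left second-stage state's subtree
  (4:red 5:blue 6:silver 7:none / 8:red 9:blue 10:none 11:none) — so a
  full-knowledge planner shows a left choice bias concentrated in
  silver-goal trials. The exact labelling used in the original experiment is
  not published; the map is a config field, and the package reproduces the
  sign of the bias, not any particular magnitude.
* **Wiring.** Each second-stage action covers two adjacent outcomes with
  wrap-around overlap, so all eight outcomes remain reachable from four
  actions and the low-complexity subset (L1, R1) still spans the subtree.
* **Session lengths.** Schedules are composed of whole blocks and stop at
  the first block that reaches the 80-trial target, so generated sessions
  average ≈ 82 trials (the mean renewal overshoot of ~2 trials); block-length
  invariants take precedence over hitting the target exactly.

## Learners

**Model-based (FORWARD).** Two-entry transition rows T(s,a,·) start uniform
and move toward the observed successor by a delta rule with learning rate
η_MB on the state-prediction error SPE = 1 − T(s,a,s′); the sibling entry
absorbs the complement so rows stay on the simplex. Action values are
recomputed every trial (token values change) by backward induction: outcome
value = token value × reward probability; stage-2 Q = expectation under T;
stage-1 Q = expectation of the maximum over the stage-2 actions available
under the block's complexity.

**Model-free (SARSA).** Q tables start at zero and update on reward
prediction errors, bootstrapping on the actually taken next action (the
recorded one during fitting). Three goal-driven forms: `1MF` (one shared
table), `3Q` (state × action × goal table, one learning rate), `3MF` (three
independent tables, three rates). The goal context is the argmax-value token
of the trial; ties are broken by the fixed order red < blue < silver (ties
have positive probability under integer token values).

## Arbitration

The control weight P_MB follows the two-state dynamics

    dP_MB/dt = α (1 − P_MB) − β P_MB,

integrated with one forward-Euler step per trial (the trial is the natural
time unit) and clamped to [0, 1]; P_MB starts at 0.5 each session. The rates
are logistic functions of the *other* system's reliability,
α(x) = A / (1 + exp(B x)) with x the MF reliability, and β likewise with the
MB reliability. Complexity can modulate a rate through the code z (1/2 for
low/high complexity under excitatory modulation, 2/1 under inhibitory):
Interaction1 puts z inside the exponent, A / (1 + exp(B(1 + cz)x));
Interaction2 scales the amplitude, A z / (1 + exp(B x)). Modulation can
apply to both rates or to one direction only; unmodulated directions use the
Null form. Forcing z ≡ 1 makes every Interaction2 variant bit-identical to
the Null (uncertainty-only) baseline, which the suite asserts.

**Reliability estimator.** The upstream formulation delegates reliability to
an earlier model and does not restate it, so the estimator here is a
declared stand-in, isolated behind one interface: each prediction error is
discretised into zero/nonzero categories and pushed into a sliding window of
10 events (two per trial per system); reliability is the Dirichlet(1)
posterior mean of the zero-error category, (n_zero + 1)/(n + 2), giving 1/2
on an empty window. RPEs are normalised by the maximum token value (10) and
thresholded at 0.1. SPEs are thresholded at **0.3**: the threshold must sit
between the asymptotic SPE of a learned (0.9, 0.1) transition (0.1 on the
common successor) and the 0.5 of a maximum-entropy transition, otherwise MB
reliability cannot discriminate the two uncertainty conditions and the
documented mechanism — uncertainty lowering MB reliability and pushing
control toward MF — is structurally disabled. A threshold of exactly 0.1
leaves zero margin for incomplete learning and was rejected on those
grounds.

**Choice.** Integrated values Q = P_MB·Q_MB + (1 − P_MB)·Q_MF enter a
softmax with inverse temperature τ(z) = tau_base × m(z), where m is (1, 1)
for no exploration effect, (1, ½) for more exploration under high
complexity, (½, 1) for the opposite. The (1, ½) pair is treated as a
multiplier on a fitted base temperature, since behaviour fixes the scale.
The block's complexity applies at both stages (the stage-1 option count
never changes, but the condition does).

## Model space and fitting

3 MF forms × 13 transition-modulation levels (Null + 2 interactions × 2
signs × 3 directions) × 3 exploration effects = 117 variants, enumerated in
a fixed lexicographic order with string ids like `3Q_int2_exc_mf2mb_explore`
(aliases `lee2014` for the uncertainty-only baseline `1MF_null_noexp`, and
`best` for that id). Free parameters per variant: η_MB, one or three η_MF,
A per direction, a shared steepness B, c (Interaction1 only), tau_base.
Fitting bounds (not published upstream, config-overridable):
η ∈ (0, 1), A ∈ (0, 1], B ∈ (0, 100], c ∈ [−10, 10], tau_base ∈ (0, 10].

Likelihoods replay each session deterministically (agents reset at session
boundaries) and accumulate the log softmax probability of both recorded
choices per trial. The replay exists twice on purpose: a numba-compiled
kernel used for fitting (microseconds per evaluation) and a pure-Python
agent used for simulation; the suite asserts their per-choice probabilities
agree to 1e-10 and checks both against a hand-rolled trial loop.

Per-subject fits use multi-start bounded L-BFGS-B (default 20 starts: the
bounds midpoint plus 19 uniform draws; seeded). Evidence is BIC-based,
log-evidence = −BIC/2 with BIC = 2·NLL + k·log(2·n_trials); the exact
evidence approximation used upstream is unstated, and BIC is the standard
desk-scale choice. Group comparison uses random-effects Bayesian model
selection: variational Dirichlet updates (prior concentration 1, tolerance
1e-6) and exceedance probabilities from 1e5 Monte-Carlo Dirichlet draws.
The variational posterior coincides with the exact conjugate closed form in
the symmetric and dominance regimes (asserted); in intermediate-evidence
regimes it is an approximation (pinned at its ~0.05 observed gap in the
unit suite).

## Behavioral metrics

**Choice optimality** scores each choice by the ideal agent's normalised
value of the chosen action, where the ideal agent plans by exact backward
induction under the *true* block transition probabilities. The stage-2 score
is doubled in high-complexity blocks, which makes a uniform-random agent's
expected score exactly 0.5 in both complexity conditions (the stage-1 option
count never changes, so the correction applies only where the denominator
doubles). Per-trial optimality averages the two stages by default
(configurable to either stage). Trials whose available ideal values are all
zero are excluded; timeout trials are excluded from all metrics.

**Bias / consistency / switching.** Stage-1 P(left) − P(right) and
previous-choice repetition are reported per goal condition (trials binned by
the argmax-value token). Switch rates are conditioned on goal change
(argmax token differs from the previous trial), with a switch-to-better
variant that also requires the new choice to have the higher ideal value.

**Condition-effect GLM.** Per subject, choice optimality is regressed (OLS)
on standardized uncertainty, complexity, mean token value, previous stage-1
choice and maximum token value; rank-deficient designs drop the offending
columns and are flagged. Effect recovery correlates per-subject effect
sizes between a dataset and the fitted model replayed on the same trials.

## Synthetic cohorts and recovery

Cohorts default to the study scale (24 subjects, 5 × 80 trials) and scale
down freely. Generative parameters are drawn per subject from ranges
narrower than the fitting bounds — η ∈ [0.05, 0.8], A ∈ [0.1, 1],
B ∈ [1, 10], tau_base ∈ [0.1, 1], c ∈ [−2, 2] — because most of the full
bound volume is degenerate (a logistic with B ≫ 10 is flat over the
reliability range actually visited; tau_base near 10 makes choices
deterministic), and fitted subjects do not live there. Ground truth is
written to a JSON sidecar next to each dataset.

What the generator does *not* emulate: reaction times, timeout/random-choice
trials (representable in the schema but not generated), any particular human
subject's parameter distribution, and the exact scanner token map. Passing
recovery tests therefore demonstrate internal consistency of the pipeline
under plausible parameter regimes, not claims about human data.

Recovery harnesses: parameter recovery (simulate under known parameters,
refit, report per-parameter Pearson r and bias) and model recovery (exceedance
confusion matrix over a candidate subset). On a 20-subject × 400-trial
cohort the learning rates, rate amplitudes and temperature recover with
positive correlations; the steepness B is reported but not counted as
identifiable a priori — reliabilities occupy a narrow band, so B trades off
against the amplitudes.

Problem sizes used by the shipped test suite: the expensive path is one
20-subject × 400-trial cohort fitted by 5 variants × 20 starts (~2 minutes),
shared by the model-recovery, parameter-recovery and P_MB condition-effect
checks; the MB-vs-MF choice-optimality comparison uses 100 runs of 2 × 80
trials per reference agent.

## Known limitations

* The reliability estimator is a stand-in for an unpublished formulation;
  window length, categories and thresholds are exposed for sensitivity
  analysis.
* Condition effects on P_MB are strongly low-pass filtered by the short
  blocks (3–7 trials) relative to the reliability window (5 trials) and the
  Euler time constant 1/(α+β); with broadly sampled generative parameters
  the uncertainty main effect and the uncertainty × complexity attenuation
  are small and subject-noise dominated, and the attenuation's sign is
  additionally biased by the asymmetric block lengths (effects measured in
  longer high-uncertainty blocks are less diluted). The corresponding
  direction checks reproduce robustly only for the complexity effect.
* Hierarchical (empirical-Bayes) fitting across subjects is out of scope;
  fits are independent per subject.
* BIC is the only evidence approximation offered.
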