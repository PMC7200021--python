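# Methods

## The world

The environment is an unbounded 2-D plane with a single chemical source.
The chemical field is radially symmetric and strictly decreasing with
distance, so the only observable — the *sign* of the spatial gradient
along the agent's heading — reduces to a facing test: positive iff the
heading has a strictly positive dot product with the vector to the
source. A zero dot product (exactly tangential heading, or an agent
sitting exactly on the source) is negative by convention; the case has
measure zero and the convention only pins down determinism. No
concentration values are ever computed, and there are no boundaries or
obstacles.

Actions: **run** advances exactly one length unit along the heading;
**tumble** redraws the heading uniformly on [0, 2π) and leaves the
position unchanged. Far from the source (≥ 100 units) a run step flips
the gradient sign with probability well under 2%, so the effective
far-field dynamics are: running preserves the gradient sign, tumbling
resamples it with probability ~1/2. Within a few units of the source the
sign flips every few steps. Both regimes matter below.

Every phase (learning episode or test) starts at 400 units from the
source at a uniformly random placement angle and heading. One
`numpy.random.Generator` drives everything in a replicate, with a fixed
draw order (placement angle, heading, then per step: tumble headings in
the environment update and the agent's action draw), so replicates are
bit-reproducible from `base_seed + replicate`.

## The agent

A discrete POMDP active-inference agent with two hidden states (positive
/ negative local gradient), two observations and two controls, written
for general dimensions. Its generative model holds an identity likelihood
λ (the observation reports the hidden state unambiguously), Dirichlet
priors Dir(α) on each column of the action-conditioned transition tensor
θ (columns indexed by previous state), and a log preference vector
ρ = ln P(o). Beliefs are mean-field: φ_s over the current state, φ_u over
the current control, φ_α the Dirichlet posterior counts.

Per step, in order: state inference (softmax of log likelihood plus the
digamma-based expected-log-transition message from the previous belief
under the executed action; a uniform message at t = 0), control
inference, the Dirichlet count update for the transition that produced
the current observation (skipped at t = 0 and when learning is
disabled), and action sampling from φ_u. The posterior over controls is
the softmax of a per-control score:

| strategy     | score |
|--------------|-------|
| efe          | epistemic + δ · instrumental |
| instrumental | instrumental |
| epistemic    | epistemic |
| random       | 0 (uniform) |

with epistemic value φ_{s,τ}·W^u·φ_s (W from inverse Dirichlet counts;
non-negative, vanishing as counts grow) and instrumental value φ_o·ρ for
the one-step-ahead predictions φ_{s,τ} = E[θ^u]·φ_s, φ_o = λ·φ_{s,τ}.
The weight δ appears only inside the efe combination, where it keeps the
instrumental term in the same range as the epistemic term; the
single-term strategies use their raw scores. The planning horizon is one
step; state epistemic value (salience) is identically zero here because
the likelihood is unambiguous, and is omitted.

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| ξ (learning rate) | 0.001 | counts per step | total Dirichlet count grows by exactly ξ per learning step |
| δ (instrumental weight) | 0.1 | — | tempers the instrumental term inside the efe score only |
| ρ (log preferences) | (0, −60) | nats | preference for positive gradients; reversed variant (−60, 0) |
| c (prior concentration) | 0.5 | counts per column | each prior column is c × a flat-Dirichlet draw |
| start distance | 400 | length units | initial distance from the source, every phase |
| episode length | 1000 | steps | learning runs are split into episodes of this length |
| test length | 1000 | steps | post-learning test under the efe strategy, learning off |
| success threshold | 50 | length units | displacement toward the source counted as chemotaxis (strict >) |
| ε_floor | 1e−16 | — | floor on likelihood entries before logs |
| transition-message floor | ln 1e−14 | nats | see numerical choices |
| ε_prune | 1e−6 | counts | stands in for a zero prior count in model reduction |

ξ and δ are fixed across all simulations. ρ's magnitude and c are free
scales with no independently observable meaning; they jointly set (i) how
decisive a learned policy is (softmax gap ≈ δ·|ρ|·Δprediction for the
efe score, |ρ|·Δprediction for the instrumental strategy), (ii) the
initial size of the novelty term (≈ 1/c), and (iii) how fast data
overwhelms the prior (ξ·steps against c). The defaults were chosen once
so that all three are in a biologically sensible regime: a well-learned
model produces near-deterministic run-in-positive / tumble-in-negative
behaviour, novelty decays over hundreds of steps, and a few hundred to a
thousand learning steps reshape the prior. Much weaker preferences make
every strategy an unbiased coin-flipper that cannot chemotax at all;
much stronger ones collapse the efe strategy onto the instrumental one.

Learning runs longer than one episode (e.g. the 4,000-step bad-bootstrap
phase) are split into 1,000-step episodes, each from a fresh random
placement, with beliefs carried across episodes. This matches the
placement protocol of every other phase and keeps learning in the
far-field regime: in a single continuous episode a successful
goal-directed agent reaches the source within ~600 steps and then spends
thousands of steps in the near-source regime where running flips the
gradient sign constantly, which overwrites its far-field transition
statistics and destroys subsequent long-range chemotaxis — an artifact
of dwell time, not of the learning rule.

## The maladaptive model

`make_maladaptive_model` constructs the canonical bad-bootstrap prior:
positive-gradient columns (0.1, 0.4) for run and (0.4, 0.1) for tumble —
believed probabilities of *staying* in a positive gradient of 0.2 vs 0.8
— and symmetric negative-gradient columns (0.25, 0.25). The mirrored
positive columns share total counts, so the novelty columns coincide and
epistemic value is initially identical for both actions, while
instrumental value favours tumbling; the column totals match the scale
of randomly initialized priors so the novelty term has the headroom the
escape dynamics require.

## Measurement

- **True model**: the 2×2×2 transition tensor estimated by running
  uniformly random actions (default 10⁶ steps in 1,000-step episodes
  from the standard placement), tallying observation transitions,
  adding one to every cell and normalizing columns. Smoothing guards the
  never-observed far-field sign flips.
- **Model accuracy**: Σ over the four (previous state, action)
  conditionals of KL(true ‖ learned posterior mean), in nats. This
  direction penalizes learned models that assign low mass to truly
  probable transitions.
- **Distribution change**: per conditional, KL(final mean ‖ initial
  mean) — the Bayesian-surprise convention.
- **Active/passive error**: after learning, the agent keeps acting and
  learning under its strategy; each step, conditioning on the one-hot of
  the current observation (valid because λ is identity), the active
  error is the MSE between the agent's predicted next-state distribution
  for its self-determined action and the true model's; the passive error
  uses a uniformly random action instead. Both accumulate over 1,000
  steps.
- **Test phase**: 1,000 steps under the efe strategy with learning
  disabled, from a fresh standard placement; beliefs are copied so the
  caller's counts are never mutated. Success = displacement toward the
  source strictly greater than 50 units.
- **Model reduction**: for prior counts α accrued into posterior counts
  φ_α, the evidence change of a reduced prior α′ is
  ΔF = ln B(φ_α) − ln B(α) + ln B(α′) − ln B(φ_α + α′ − α), evaluated per
  independent Dirichlet column and summed (the prior is a product of
  column Dirichlets, so this is exact). The prune scan reduces each of
  the eight tensor entries to ε_prune one at a time; a parameter is
  pruned iff ΔF < 0 strictly — a tie (ΔF = 0, which occurs identically
  for any entry of a column with zero posterior accrual) is never
  pruned. The protocol learns 500 steps, promotes the posterior to the
  prior, learns 500 more from a fresh placement, then scans.

## Numerical choices

- λ's zeros are floored at 1e−16 before logs; softmax then recovers the
  one-hot limit.
- The expected-log-transition message in state inference is floored at
  ln 1e−14, slightly above ln ε_floor. Without this, a Dirichlet count
  below ~0.03 makes the digamma message (≈ −1/count) stronger than the
  floored log likelihood, so state inference can contradict an
  unambiguous observation and learning mis-attributes transitions
  (inverting the learned model). The floor guarantees the likelihood
  always dominates, for any positive counts.
- ΔF is computed as paired differences, ln B(φ_α) − ln B(α) plus
  ln B(α′) − ln B(φ_α + α′ − α), with the merged count associated as
  α′ + (φ_α − α); both differences then cancel bitwise when φ_α = α, so
  exact ties are exactly zero rather than gammaln round-off noise (which
  would otherwise randomly mark unlearned parameters as pruned).
- Softmax temperature is 1 everywhere and actions are sampled, never
  argmaxed. ΔF ties, the observation tie (dot product exactly 0) and the
  t = 0 message are the only tie-break conventions in the package.

## What the simulator does and does not emulate

The generator *is* the study system: all data are simulated. The world
captures the logic of run-and-tumble chemotaxis — sign-only gradient
sensing as a function of space, persistence while running, memoryless
reorientation — and nothing else: no receptor kinetics or adaptation, no
temporal gradient comparison, no rotational diffusion during runs, no
3-D geometry, no boundaries, no multiple sources. Conclusions about
*learning dynamics* (which action strategies learn usable, parsimonious
or trapped models) are the intended scope; the package says nothing
about quantitative bacterial motility.

Known behaviours of the system worth keeping in mind:

- With two states, random exploration is near-optimal, so the epistemic
  and random strategies learn models of statistically indistinguishable
  accuracy, and their active prediction errors coincide to within
  Monte-Carlo error. The agent code is written for general state-space
  sizes, where directed exploration should separate from random.
- A randomly initialized prior can contain near-zero counts whose frozen
  novelty dominates the test-phase policy, so the duration-0 baseline
  performance is noisy across seed batches (its mean sits near the start
  distance with heavy tails both ways).
- Instrumental-strategy performance stops improving after a few hundred
  learning steps and plateaus far above the other strategies' asymptote,
  but the plateau does sit visibly below the duration-0 baseline; the
  improvement comes from the untrapped majority of replicates.
- Under the strict tie rule, parameters in never-visited conditionals
  cannot be pruned (their ΔF is exactly zero), so pruning totals track
  how many deterministic-outcome conditionals a strategy visited with
  imbalanced accrual; exploratory strategies therefore prune at least as
  many parameters as goal-directed ones in this world.

## Problem sizes

Replicated experiments default to 300 replicates per condition (the CLI
scale). The test suite runs the same protocols at 25–100 replicates per
condition, sizes at which every asserted ordering is stable across seed
batches; the acceptance script runs the bad-bootstrap experiment at the
full 300.
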