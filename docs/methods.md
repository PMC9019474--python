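# Methods

This note records the model, the optimization procedures, the numerical
conventions, and the design choices behind `cbfe`, in the spirit of a methods
appendix.  Everything quantitative stated here is computed by the test suite
or the acceptance script; nothing is asserted from memory.

## 1. Objectives

All free energies are reported in bits.  Internal computation may use natural
logarithms; conversion happens at the reporting boundary.

**Variational / Bethe free energy.**  For a factorized model
`f(s) = ∏_a f_a(s_a)` the Bethe assumption factorizes the variational
distribution into per-factor joint beliefs `q_a` and per-variable marginals
`q_i` with counting numbers `1 − d_i`, where the degree `d_i` is the number of
factor beliefs containing variable `i`.  The package evaluates

```
B[q] = Σ_a U[q_a ‖ f_a] − Σ_a H[q_a] − Σ_i (1 − d_i) H[q_i]
```

directly from a belief state.  On acyclic (tree) models the sum-product fixed
point makes this exact: the minimized BFE equals `−log₂ Z` with
`Z = Σ f(s)`.  All planning models built by this package are trees once
candidate policies are clamped, so every reported planning value is a global
optimum rather than a loopy approximation.

**Constrained BFE.**  The CBFE adds point-mass constraints
`q(y_k) = δ(y_k − ŷ_k)` on the predicted future observations.  Substituting
the optimized outcomes `ŷ` into the factor tables gives

```
B[q; û, ŷ] = U[q(x) ‖ f(ŷ, x | û)] − H_B[q(x)],
```

with delta beliefs contributing zero entropy.  At the optimum over `q` on a
tree this collapses to `−log₂ [ p(ŷ | û) · p̃(ŷ) ]`, which is the closed form
the oracle uses (§4).

**Expected free energy.**  The EFE is evaluated by the standard forward-only
discrete recipe: roll the state belief forward through the policy's
transition tables, project through the observation table, and sum per-step
ambiguity (expected column entropy of the observation model) and risk (KL of
the predicted outcome distribution from the goal prior).  The original
formulation's appendix-level procedural details are not available in our
source material; the ambiguity + risk form is the implemented definition, and
any discrepancy is confined to the EFE evaluator.  Policy selection for all
objectives is pure argmin — no policy-precision/temperature optimization
(equivalently, a large fixed precision).

## 2. Optimization

**Message passing.**  Inference uses the bipartite factor–variable
representation (equivalent to Forney-style graphs for all Bethe bookkeeping).
`make_schedule` topologically orders every factor→variable message so that on
trees one iteration performs a full forward sweep plus the complete backward
(smoothing) sweep; on cyclic graphs the residual messages are appended in
deterministic order and the schedule is iterated.  All messages default to
the sum-product rule, which is exact on the tree-structured planning models;
variational updates are implemented and selectable per schedule entry for
hybrid schedules, but the exact-on-trees default avoids guessing an
unspecified rule mix.

**Point-mass (EM) iteration.**  With point-mass constraints the optimizer
alternates message sweeps (E-step) with MAP updates of each constrained
variable: the new `ŷ_k` is the argmax of the elementwise product of its
incoming messages (M-step).  Initialization is the argmax of the
unconstrained predictive marginal after one sum-product sweep —
deterministic and reproducible.  Convergence requires unchanged assignments
and a maximum marginal change ≤ `tol` (default 1e−8, `max_iters` 50);
non-convergence returns the best state with a flag rather than raising.

**Exhaustive mode.**  Because EM can in principle stall in local optima, the
default CBFE minimizer enumerates all outcome configurations whenever their
number is ≤ 4096 (the T-maze has 16² = 256), performs exact inference per
configuration, and returns the global optimum; EM remains the scalable
algorithm and, on the T-maze, empirically reaches the same optima (tested).
The interactive protocol uses the closed-form oracle evaluator (§4) for
speed; its equivalence to the message-passing routes is pinned by tests.

**Tie-breaking.**  Everywhere deterministic: lowest index for outcome
updates, lexicographically lowest configuration/policy for optima.  Ties are
scientifically meaningful (e.g. the two informative T-maze policies are
genuinely on equal footing before the cue is read) and are surfaced as tied
optimal sets.  Planning additionally offers a seeded uniform-random
tie-break, which the interactive experiments use so that an ambivalent agent
splits between tied arms instead of always taking the lowest-numbered one.

## 3. Numerical conventions

- `0 · log 0 := 0`.  Probabilities are never clipped: belief mass on a
  zero-probability configuration propagates `+inf` energy, marking infeasible
  policies/outcomes instead of hiding them behind an ε.
- Distribution construction renormalizes exactly after validating the sum to
  1 within 1e−9; factor tables are validated to 1e−6 and then column-
  normalized exactly.
- Categories are 0-based internally; the T-maze API uses the field's 1-based
  position labels for controls, so policies read like `(4, 3)`.
- Bethe consistency (factor beliefs marginalizing to variable marginals) is
  tested to 1e−6 at convergence; decomposition identities to 1e−6; oracle
  equivalences to 1e−9.
- Joint-enumeration routines (oracles, Eq.-34/36-style decomposition terms)
  refuse domains above 2²⁴ configurations.

## 4. Oracles and dual routes

`oracle_cbfe` and `oracle_log_partition` compute their quantities by dense
tensor enumeration of the joint (numpy broadcasting), independent of the
message-passing engine.  The tests hold three equivalences: BP marginals =
brute-force enumeration on random trees; exhaustive-mode CBFE = closed-form
`min_ŷ −log₂[p(ŷ|û) p̃(ŷ)]`; minimized BFE on trees = `−log₂ Z`.  The slide
(perception) step is likewise checked against brute-force Bayes.

## 5. The testbeds

**Bandit.**  One binary observation, two levers, no goal prior; the
conditional table is `[[0.5, 1], [0.5, 0]]` (columns = levers).  The minimized
BFE is 0 bits for both levers while the CBFE charges the ignorant lever 1 bit
— the minimal demonstration that the point-mass constraint, not the reward,
produces the epistemic preference.

**T-maze.**  States are position × reward-arm (8, position-major), built with
Kronecker products so controls act on position only and arms 2/3 are
absorbing; observations are position × outcome (16, position-major) with the
block-diagonal observation matrix `A1 ⊕ A2 ⊕ A3 ⊕ A4`.  The start outcome is
uninformative (½/½), the cue deterministic, and an arm yields "reward
obtained" with probability α when correct and 1 − α otherwise.  Goal priors
put `softmax(0, 0, c, −c)` on the outcomes, spread evenly over positions; the
Kronecker spread is renormalized, which shifts every policy's extrinsic value
by the same constant and cannot change any argmin.

**Goal-prior schedule (design choice).**  The schedule is anchored to
*absolute* time: flat at t = 1 ("freedom to explore" on the very first move),
informative at every later step.  The alternative — flat at the first step of
*every* replanning round — makes the receding-horizon agent perpetually defer
reward (at round 2 it would prefer to linger at the cue, since its immediate
step carries no goal value), which contradicts the intended cue-then-reward
behavior.  The schedule is a per-round input (a callable of absolute time),
and an `all_informative` mode applies the informative prior at every step
including the first; under it the CBFE agent turns greedy, guessing an arm
immediately, and its mean reward drops to ≈ 0.5 in the otherwise rewarding
region — the acceptance script measures exactly this.

**Environment (generative process).**  The simulator shares the `A` and `B`
tables with the generative model: the agent is well-specified by
construction.  Consequences: a green interactive test establishes that the
objectives produce the intended behavior *under a correct model*; it says
nothing about robustness to model–process mismatch (explicitly out of
scope).  Position-1 process outcomes are sampled from the model's `A1` column
(½/½), an assumption since only the model side pins this down.  The reported
"reward" per episode is the *expected* reward probability of the final
position (α at the correct arm, 1 − α at the wrong arm, 0 elsewhere), so
episode averages estimate the mean reward probability directly; residual
episode-to-episode variance comes from stochastic cue-free trajectories and
random tie-breaks, and the interactive tests use 3σ binomial bands at ≥200
episodes.

## 6. Known limitations

- Continuous variables (and the differential entropy of Dirac deltas),
  hierarchical/deep models, policy-precision optimization, sophisticated
  inference, and learning of the model tables are all out of scope.
- Loopy graphs run plain iterated BP without damping or convergence theory;
  the package targets tree-structured planning models.
- The EFE evaluator implements the ambiguity + risk form only (§1).
- Exhaustive/oracle routes require enumerable outcome domains; beyond the
  caps, only EM (for the CBFE) is available and global optimality is no
  longer guaranteed.
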