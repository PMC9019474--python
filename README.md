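# cbfe — epistemic active inference on discrete factor graphs

`cbfe` is a Python library for **planning as free-energy minimization** in
discrete generative models, built around the **constrained Bethe free energy
(CBFE)**: belief propagation on a factor graph with *point-mass (delta)
constraints* on predicted future observations.  It is aimed at computational
neuroscientists and cognitive modellers who want epistemic (information
seeking) agents without hand-deriving objective-specific update equations —
the whole pipeline is ordinary message passing on the generative model.

## The idea

An active-inference agent holds a generative model of future observations
`y`, hidden states `x` and controls `u`,

```
f(y, x | u) = p(x_{t-1}) ∏_k p(y_k | x_k) p(x_k | x_{k-1}, u_k) p̃(y_k),
```

where `p̃(y_k)` are *goal priors* biasing the model toward desired outcomes.
For each candidate policy `û` (a fixed control sequence) the agent minimizes a
variational free energy over the future and picks the argmin policy.  Three
objectives are implemented, all in bits:

- **BFE** — the Bethe free energy
  `B[q] = Σ_a U[q_a‖f_a] − Σ_a H[q_a] − Σ_i (1−d_i) H[q_i]`,
  minimized by the sum-product algorithm.  Exact on the tree-structured
  planning models used here (minimized BFE = −log₂ Z), but *blind to
  information*: it never prefers policies that resolve uncertainty.
- **CBFE** — the BFE under the additional constraint
  `q(y, x) = q(x) δ(y − ŷ)`: the agent *knows it will observe something*,
  and the potential outcomes `ŷ` are optimized alongside the beliefs,
  `B[q; û, ŷ] = U[q(x) ‖ f(ŷ, x | û)] − H_B[q(x)]`.
  Minimization is an EM-style alternation of message sweeps and MAP updates
  of `ŷ` (with an exhaustive global-optimum mode for small outcome domains).
  Self-evidencing over `ŷ` yields an epistemic drive.
- **EFE** — the expected free energy in its forward-only
  ambiguity + risk form,
  `G[û] = Σ_k E_{q(x_k)} H[p(y_k|x_k)] + KL[q(y_k) ‖ c_k]`,
  the classic comparison point.

The CBFE total decomposes as
`−confidence + complexity − extrinsic value` or equivalently as
`posterior divergence − intrinsic value − extrinsic value`, and the package
evaluates both (plus the analogous BFE decomposition) with their summation
identities checked to 1e−6.

Two classic testbeds ship as first-class model builders: a **two-armed
bandit** (one lever informative, one ignorant, no reward) and the **T-maze**
(start, two absorbing reward arms, and a cue location that reveals the reward
arm), together with a simulated T-maze environment and the full interactive
plan → act → execute → observe → slide protocol.

## Worked example

The bandit makes the epistemic gap visible in two numbers.  Lever `u = 0`
yields either outcome with probability ½; lever `u = 1` always yields outcome
0.  There is no reward, so a purely extrinsic agent has no preference:

```text
$ cbfe bandit-table
             u  BFE  CBFE
policy
ignorant     0  0.0   1.0
informative  1  0.0   0.0
```

The minimized BFE is 0 bits for both levers — it cannot tell them apart.  The
CBFE charges the ignorant lever `−log₂ p(ŷ|û) = 1` bit for its imprecise
prediction and the informative lever nothing, so the agent pulls the
informative lever purely to *know*.

On the T-maze (reward probability α = 0.9, reward utility c = 2, lookahead
T = 2):

```python
>>> from cbfe import TMazeConfig, build_tmaze_model, plan, enumerate_policies
>>> model = build_tmaze_model(TMazeConfig(alpha=0.9, c=2.0))
>>> res = plan(model.prior, model, "CBFE",
...            policies=enumerate_policies(model.controls, 2))
>>> res.optimal
[(4, 2), (4, 3)]
>>> res.table[res.selected].total_bits
7.518239917608241
```

The optimal policies visit the cue (position 4) first and a reward arm
second; they tie at 7.518 bits because the cue has not been *read* yet, so
neither arm is distinguished at planning time.  The full 4 × 4 planning grid
(first move on the rows, second on the columns, in bits):

```text
second_move       1      2      3       4
first_move
1            11.252  8.366  8.366  11.252
2             7.653  7.653  7.653   7.653
3             7.653  7.653  7.653   7.653
4            11.252  7.518  7.518  10.252
```

The CLI regenerates all the batch experiments
(`cbfe plan-grid`, `cbfe decompose`, `cbfe landscape`, `cbfe bandit-table`),
writing CSV tables and a JSON metadata sidecar, with optional `--plot`
heatmaps.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the bandit worked example (minimized CBFE for both
levers and minimized BFE for the ignorant lever, in bits) and the mean reward
probability of the interactive CBFE agent when informative goal priors are
applied at every planned step in the high-α, high-utility T-maze region
(≥200 seeded episodes of the N = 2-move protocol), and writes them as JSON.
The `--seed` argument drives every source of randomness.

## Layout

| module | contents |
| --- | --- |
| `cbfe.discrete` | categorical/point-mass distributions, entropies, divergences (bits) |
| `cbfe.factor_graph` | factor-graph structure, Bethe degrees, enumeration, YAML I/O |
| `cbfe.message_passing` | sum-product and variational updates, schedules, EM fixed point |
| `cbfe.free_energy` | BFE/CBFE/EFE evaluation, decompositions, closed-form oracles |
| `cbfe.models` | state-space engines and unrolled future models |
| `cbfe.agent` | policy enumeration, planning, slide step, interactive protocol |
| `cbfe.tmaze` | bandit and T-maze builders, simulated environment |
| `cbfe.experiments` / `cbfe.cli` | batch grids, landscapes, command-line front end |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
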