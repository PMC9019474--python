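"""Batch runners: planning grids, decomposition grids, reward landscapes.

Outputs are pandas tables (first move on the rows, second move on the
columns), written as CSV with a JSON metadata sidecar; re-running with the
same seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agent import enumerate_policies, plan, run_protocol
from .free_energy import decompose_ccx, minimize_cbfe
from .tmaze import TMazeConfig, TMazeEnv, build_tmaze_model

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioGrid",
    "NAMED_SCENARIOS",
    "planning_table",
    "planning_grid",
    "decomposition_grid",
    "reward_landscape",
    "bandit_table",
]

#: the named (alpha, c) scenarios studied on the planning grids
NAMED_SCENARIOS = ((0.9, 2.0), (0.5, 2.0), (0.9, 0.0))


@dataclass
class ScenarioGrid:
    """A rectangle of (alpha, c) scenarios for the interactive landscape."""

    alphas: list[float] = field(default_factory=lambda: list(np.round(np.linspace(0.5, 1.0, 11), 3)))
    cs: list[float] = field(default_factory=lambda: list(np.round(np.linspace(0.0, 4.0, 11), 3)))
    objectives: tuple[str, ...] = ("CBFE", "EFE")
    replicates: int = 10
    seed: int = 0
    goal_mode: str = "explore_first"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _policy_frame(values: dict[tuple, float]) -> pd.DataFrame:
    """16 policy energies as a 4x4 table, first move rows / second move cols."""
    df = pd.DataFrame(
        [[values[(r, c)] for c in (1, 2, 3, 4)] for r in (1, 2, 3, 4)],
        index=pd.Index([1, 2, 3, 4], name="first_move"),
        columns=pd.Index([1, 2, 3, 4], name="second_move"),
    )
    return df


def planning_table(cfg: TMazeConfig, objective: str, engine: str = "exhaustive"):
    """One scenario's 4x4 free-energy table plus the argmin policy set."""
    model = build_tmaze_model(cfg)
    policies = enumerate_policies(model.controls, 2)
    result = plan(model.prior, model, objective, policies=policies, engine=engine)
    values = {p: r.total_bits for p, r in result.table.items()}
    return _policy_frame(values), result.optimal


def planning_grid(
    scenarios=NAMED_SCENARIOS,
    objectives=("CBFE", "BFE", "EFE"),
    out_dir=None,
    engine: str = "exhaustive",
):
    """Free-energy planning tables for every (objective, scenario) pair."""
    out = {}
    for objective in objectives:
        for alpha, c in scenarios:
            cfg = TMazeConfig(alpha=alpha, c=c)
            table, optimal = planning_table(cfg, objective, engine=engine)
            out[(objective, (alpha, c))] = {"table": table, "optimal": optimal}
            log.info("planning %s alpha=%s c=%s argmin=%s", objective, alpha, c, optimal)
    if out_dir is not None:
        _write_grids(out, out_dir, "planning")
    return out


def decomposition_grid(scenarios=NAMED_SCENARIOS, out_dir=None):
    """Confidence / complexity / extrinsic tables of the optimized CBFE."""
    out = {}
    for alpha, c in scenarios:
        cfg = TMazeConfig(alpha=alpha, c=c)
        model = build_tmaze_model(cfg)
        tables = {t: {} for t in ("confidence", "complexity", "extrinsic")}
        for policy in enumerate_policies(model.controls, 2):
            fm = model.future(policy).constrained()
            _report, beliefs = minimize_cbfe(fm.graph, mode="exhaustive")
            terms = decompose_ccx(fm.graph, beliefs, policy).terms
            for t in tables:
                tables[t][policy] = terms[t]
        out[(alpha, c)] = {t: _policy_frame(v) for t, v in tables.items()}
    if out_dir is not None:
        for (alpha, c), tabs in out.items():
            for term, df in tabs.items():
                _to_csv(df, out_dir, f"decomposition_{term}_alpha{alpha}_c{c}.csv")
    return out


def reward_landscape(grid: ScenarioGrid, reward_arm: int = 3, out_dir=None):
    """Mean expected reward per (alpha, c) scenario per objective.

    Each cell averages the final-position expected reward over
    ``grid.replicates`` seeded episodes of the N-move interactive protocol
    with random tie-breaking among optimal policies.
    """
    seeds = np.random.SeedSequence(grid.seed).spawn(
        len(grid.objectives) * len(grid.alphas) * len(grid.cs)
    )
    out = {}
    i = 0
    for objective in grid.objectives:
        mat = np.zeros((len(grid.alphas), len(grid.cs)))
        for ai, alpha in enumerate(grid.alphas):
            for ci, c in enumerate(grid.cs):
                cfg = TMazeConfig(alpha=alpha, c=c, goal_mode=grid.goal_mode)
                rng = np.random.default_rng(seeds[i])
                i += 1
                rewards = []
                for _ in range(grid.replicates):
                    env = TMazeEnv(cfg, reward_arm=reward_arm)
                    model = build_tmaze_model(cfg)
                    rec = run_protocol(
                        model, env, objective, N=cfg.N, T=cfg.T, seed=rng,
                        engine="oracle", tie_break="random",
                    )
                    rewards.append(rec.expected_reward)
                mat[ai, ci] = float(np.mean(rewards))
                log.info(
                    "landscape %s alpha=%s c=%s mean_reward=%.3f",
                    objective, alpha, c, mat[ai, ci],
                )
        out[objective] = pd.DataFrame(
            mat,
            index=pd.Index(grid.alphas, name="alpha"),
            columns=pd.Index(grid.cs, name="c"),
        )
    if out_dir is not None:
        for objective, df in out.items():
            _to_csv(df, out_dir, f"landscape_{objective}.csv")
        _write_meta(out_dir, {"grid": grid.__dict__ | {"objectives": list(grid.objectives)}})
    return out


def bandit_table() -> pd.DataFrame:
    """The bandit worked example: minimized BFE and CBFE per lever, in bits."""
    from .free_energy import minimize_bfe
    from .tmaze import build_bandit_model

    bandit = build_bandit_model()
    rows = []
    for u, name in ((0, "ignorant"), (1, "informative")):
        fm = bandit.future((u,))
        bfe, _ = minimize_bfe(fm.graph)
        cbfe, _ = minimize_cbfe(fm.constrained().graph, mode="exhaustive")
        rows.append({"policy": name, "u": u, "BFE": bfe.total_bits, "CBFE": cbfe.total_bits})
    return pd.DataFrame(rows).set_index("policy")


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _to_csv(df: pd.DataFrame, out_dir, name: str) -> None:
    from pathlib import Path

    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    df.to_csv(p / name, float_format="%.10g")


def _write_grids(out, out_dir, prefix: str) -> None:
    meta = {}
    for (objective, (alpha, c)), entry in out.items():
        name = f"{prefix}_{objective}_alpha{alpha}_c{c}.csv"
        _to_csv(entry["table"], out_dir, name)
        meta[name] = {"optimal": [list(p) for p in entry["optimal"]]}
    _write_meta(out_dir, meta)


def _write_meta(out_dir, payload: dict) -> None:
    from pathlib import Path

    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    payload = {"cbfe_version": __version__} | payload
    (p / "metadata.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def plot_heatmap(df: pd.DataFrame, path, title: str = "") -> None:
    """Optional matplotlib heatmap mirroring the grid layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    data = df.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(data)
    im = ax.imshow(masked, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(df.columns)), [str(c) for c in df.columns])
    ax.set_yticks(range(len(df.index)), [str(r) for r in df.index])
    ax.set_xlabel(df.columns.name or "")
    ax.set_ylabel(df.index.name or "")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
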