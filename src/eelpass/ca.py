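"""Cellular-automata passage model on a classified field.

Every automaton in the cohort shares the same passability map (one burst-speed
threshold for all), moves by the priority-randomised Moore-neighbourhood rule
and is subject to the stuck/fall-back rule. Because the automata are
homogeneous, predicted efficiencies tend toward 0% or 100%: if one automaton
can thread a passable route, nearly all eventually do.

The module exposes both readable single-agent operations
(:func:`prioritized_neighbors`, :func:`step_agent`,
:func:`update_stuck_state`) — useful for inspection and testing — and the
cohort-level :func:`run_ca`, which drives the vectorised engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from . import engine
from .classify import BOUNDARY, PASSABLE, ClassifiedField
from .results import PassageResult

__all__ = ["CAConfig", "AgentRecord", "CAPassageModel",
           "spawn_agents", "prioritized_neighbors", "step_agent",
           "update_stuck_state", "run_ca"]


@dataclass(frozen=True)
class CAConfig:
    """Parameters of a CA run.

    Defaults follow the sensitivity-analysed operating point: 1000 automata,
    10 000 timesteps, stuck = net progress of at most 2 cells over 20 moves,
    30 forced fall-back moves.
    """

    n_agents: int = 1000
    max_timesteps: int = 10_000
    stuck_window: int = 20
    stuck_threshold: int = 2
    fallback_moves: int = 30
    seed: int | None = None
    stuck_assessment: str = "rolling"   # or "block" (disjoint 20-move blocks)

    def __post_init__(self) -> None:
        for name in ("n_agents", "max_timesteps", "stuck_window",
                     "fallback_moves"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.stuck_threshold < self.stuck_window:
            raise ValueError("stuck_threshold must lie in [0, stuck_window)")


@dataclass
class AgentRecord:
    """State of one automaton (single-agent reference implementation)."""

    position: tuple[int, int]
    mode: str = "normal"                # or "fallback"
    fallback_remaining: int = 0
    history: list[int] = dc_field(default_factory=list)  # streamwise positions
    moves: int = 0
    outcome: str = "active"             # passed / timed_out / active


def spawn_agents(cf: ClassifiedField, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Spawn columns for n agents on the downstream edge, uniform over wetted cells.

    Agents enter on any non-boundary cell of row ``n_streamwise - 1`` (with
    replacement — automata do not interact). Returns the spanwise index of
    each agent's spawn cell.
    """
    wet_edge = cf.classes[-1] != BOUNDARY
    return engine.spawn_edge_cells(wet_edge, n, rng)


def prioritized_neighbors(pos: tuple[int, int], cf: ClassifiedField,
                          mode: str = "normal") -> list[list[tuple[int, int]]]:
    """Moore neighbours of ``pos``, passable only, grouped by priority.

    Normal mode returns [upstream, cross-stream, downstream] groups;
    fall-back mode reverses the group order. Off-grid, boundary and
    impassable cells are removed.
    """
    n, m = cf.grid.shape
    i, j = pos
    if not (0 <= i < n and 0 <= j < m):
        raise ValueError(f"position {pos} outside grid {cf.grid.shape}")
    groups: list[list[tuple[int, int]]] = [[], [], []]  # up, cross, down
    for di, dj in engine.OFFSETS:
        ni, nj = i + int(di), j + int(dj)
        if not (0 <= ni < n and 0 <= nj < m):
            continue
        if cf.classes[ni, nj] != PASSABLE:
            continue
        groups[int(di) + 1].append((ni, nj))
    if mode == "fallback":
        groups.reverse()
    return groups


def step_agent(agent: AgentRecord, cf: ClassifiedField,
               rng: np.random.Generator) -> AgentRecord:
    """Advance one automaton by one move (reference implementation).

    The destination is drawn uniformly from the highest-priority non-empty
    group; with no candidates anywhere the automaton holds its cell (the move
    still counts). Mirrors the engine's draw mapping (floor of one uniform
    times the group size) so both implementations select identically.
    """
    if agent.outcome != "active":
        raise ValueError("agent is no longer active")
    groups = prioritized_neighbors(agent.position, cf, agent.mode)
    dest = agent.position
    u = rng.random()
    for group in groups:
        if group:
            dest = group[min(int(u * len(group)), len(group) - 1)]
            break
    agent.position = dest
    agent.moves += 1
    agent.history.append(dest[0])
    if dest[0] == 0:
        agent.outcome = "passed"
    return agent


def update_stuck_state(agent: AgentRecord, config: CAConfig) -> AgentRecord:
    """Apply the stuck/fall-back bookkeeping after a move.

    A normal-mode agent whose net streamwise progress over the trailing
    ``stuck_window`` moves is at most ``stuck_threshold`` cells switches to
    fall-back for ``fallback_moves`` moves; on exit it reverts to normal and
    its window buffer resets.
    """
    if agent.mode == "fallback":
        agent.fallback_remaining -= 1
        if agent.fallback_remaining <= 0:
            agent.mode = "normal"
            agent.history = [agent.position[0]]
        return agent
    w = config.stuck_window
    if len(agent.history) > w:
        progress = agent.history[-1 - w] - agent.history[-1]
        if progress <= config.stuck_threshold:
            agent.mode = "fallback"
            agent.fallback_remaining = config.fallback_moves
    return agent


def run_ca(cf: ClassifiedField, config: CAConfig | None = None) -> PassageResult:
    """Simulate a cohort of automata over a classified field.

    Deterministic given ``config.seed``; efficiency is the percentage of
    automata reaching the upstream edge within the timestep budget.
    """
    config = config or CAConfig()
    rng = np.random.default_rng(config.seed)
    spawn_j = spawn_agents(cf, config.n_agents, rng)
    out = engine.simulate_cohort(
        wet=cf.classes != BOUNDARY,
        static_passable=cf.passable,
        spawn_j=spawn_j,
        rng=rng,
        max_timesteps=config.max_timesteps,
        stuck_window=config.stuck_window,
        stuck_threshold=config.stuck_threshold,
        fallback_moves=config.fallback_moves,
        cell_size=cf.grid.cell_size,
        stuck_assessment=config.stuck_assessment,
    )
    meta = {
        "threshold_ms": float(cf.threshold),
        "seed": config.seed,
        "max_timesteps": config.max_timesteps,
        "stuck_window": config.stuck_window,
        "stuck_threshold": config.stuck_threshold,
        "fallback_moves": config.fallback_moves,
        **{k: v for k, v in cf.meta.items() if np.isscalar(v)},
    }
    return PassageResult(model="ca", outcomes=out.outcomes, moves=out.moves,
                         spawn_j=spawn_j, meta=meta)


class CAPassageModel:
    """Object-style wrapper: bind a classified field, run cohorts from it."""

    def __init__(self, cf: ClassifiedField, config: CAConfig | None = None):
        self.cf = cf
        self.config = config or CAConfig()

    def run(self, seed: int | None = None) -> PassageResult:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        return run_ca(self.cf, cfg)
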