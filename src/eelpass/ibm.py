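"""Individual-based passage model with heterogeneous burst speeds and exhaustion.

Each agent is assigned a burst swimming speed once, drawn from the lognormal
fitted to the quantile triple for its body length, and keeps it for life.
Movement mechanics are the CA's, but passability is per agent — a destination
is viable for an upstream or cross-stream move only if the agent's burst
speed strictly exceeds the water speed at the destination centroid — and
every move costs time:

    upstream / cross moves:  t = d / (v - u)
    downstream (fall-back):  t = d / (v + u)   (flow-assisted)

with d the centroid distance (cell size, times sqrt(2) for diagonals), v the
agent's burst speed and u the water speed at the destination. An agent whose
accumulated swim time exceeds the burst-endurance budget (20 s by convention)
is exhausted and fails. An agent with no viable destination holds its cell
without accruing time — holding is not bursting — until the stuck rule sends
it falling back.

Because flow conditions are approximately uniform along the pass, a passed
agent's ascent time extrapolates linearly to the longest pass it could have
ascended within the budget: L_max = L_simulated * T_burst / t_ascent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import engine
from .flowfield import VelocityField
from .results import PASSED, PassageResult
from .swim import BurstSpeedDistribution, EnduranceBudget, sample_speeds

__all__ = ["IBMConfig", "IBMPassageModel", "viable_neighbors", "move_time",
           "run_ibm", "max_pass_length"]


@dataclass(frozen=True)
class IBMConfig:
    """Parameters of an individual-based run (CA parameters plus endurance)."""

    n_agents: int = 1000
    max_timesteps: int = 10_000
    stuck_window: int = 20
    stuck_threshold: int = 2
    fallback_moves: int = 30
    seed: int | None = None
    stuck_assessment: str = "rolling"
    burst_duration: float = 20.0          # s of burst swimming available
    diagonal_factor: float = math.sqrt(2.0)
    fallback_time_mode: str = "assisted"  # or "free": zero-cost fall-back

    def __post_init__(self) -> None:
        for name in ("n_agents", "max_timesteps", "stuck_window",
                     "fallback_moves"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.stuck_threshold < self.stuck_window:
            raise ValueError("stuck_threshold must lie in [0, stuck_window)")
        if not self.burst_duration > 0:
            raise ValueError("burst_duration must be positive")
        if self.fallback_time_mode not in ("assisted", "free"):
            raise ValueError("fallback_time_mode must be 'assisted' or 'free'")


def viable_neighbors(pos: tuple[int, int], field: VelocityField,
                     burst_speed: float, mode: str = "normal"
                     ) -> list[list[tuple[int, int]]]:
    """Moore neighbours grouped by priority, per-agent viability applied.

    Equivalent to classifying the field at threshold ``burst_speed`` for
    upstream/cross moves (strict inequality: a destination exactly at the
    agent's burst speed yields no headway); downstream destinations need only
    be wet.
    """
    n, m = field.grid.shape
    i, j = pos
    if not (0 <= i < n and 0 <= j < m):
        raise ValueError(f"position {pos} outside grid {field.grid.shape}")
    groups: list[list[tuple[int, int]]] = [[], [], []]
    for di, dj in engine.OFFSETS:
        ni, nj = i + int(di), j + int(dj)
        if not (0 <= ni < n and 0 <= nj < m):
            continue
        u = field.speed[ni, nj]
        if np.isnan(u):
            continue
        if di <= 0 and not burst_speed - u > 0:
            continue
        groups[int(di) + 1].append((ni, nj))
    if mode == "fallback":
        groups.reverse()
    return groups


def move_time(distance: float, burst_speed: float, water_speed: float,
              direction: str, fallback_time_mode: str = "assisted") -> float:
    """Time for one move from the agent/water relative speed.

    Upstream and cross-stream moves require positive headway
    (burst_speed > water_speed); downstream moves are flow-assisted.
    """
    if direction in ("upstream", "cross"):
        rel = burst_speed - water_speed
        if not rel > 0:
            raise ValueError(
                f"non-positive relative speed on an {direction} move "
                f"(burst {burst_speed}, water {water_speed})"
            )
        return distance / rel
    if direction == "downstream":
        if fallback_time_mode == "free":
            return 0.0
        return distance / (burst_speed + water_speed)
    raise ValueError("direction must be 'upstream', 'cross' or 'downstream'")


def max_pass_length(ascent_time: float, simulated_length: float,
                    budget: EnduranceBudget = EnduranceBudget()) -> float:
    """Longest pass ascendable within the burst budget, by linear scaling."""
    if not ascent_time > 0:
        raise ValueError("ascent_time must be positive")
    return simulated_length * budget.burst_duration / ascent_time


def run_ibm(field: VelocityField, dist: BurstSpeedDistribution,
            config: IBMConfig | None = None) -> PassageResult:
    """Simulate a cohort of heterogeneous agents over a velocity field.

    Each agent samples its burst speed once at creation, then ascends under
    the shared movement mechanics with per-move time accounting. Outcomes are
    passed, exhausted (swim time exceeded the budget) or timed out. Passed
    agents carry their ascent time and extrapolated maximum pass length.
    """
    config = config or IBMConfig()
    rng = np.random.default_rng(config.seed)
    wet = ~field.nodata
    spawn_j = engine.spawn_edge_cells(wet[-1], config.n_agents, rng)
    burst = sample_speeds(dist, config.n_agents, rng)
    out = engine.simulate_cohort(
        wet=wet,
        speed=field.speed,
        burst=burst,
        spawn_j=spawn_j,
        rng=rng,
        max_timesteps=config.max_timesteps,
        stuck_window=config.stuck_window,
        stuck_threshold=config.stuck_threshold,
        fallback_moves=config.fallback_moves,
        cell_size=field.grid.cell_size,
        burst_duration=config.burst_duration,
        diagonal_factor=config.diagonal_factor,
        fallback_time_mode=config.fallback_time_mode,
        stuck_assessment=config.stuck_assessment,
    )
    passed = out.outcomes == PASSED
    ascent = np.where(passed, out.elapsed_s, np.nan)
    length = field.grid.length
    l_max = np.zeros(config.n_agents)
    ok = passed & (out.elapsed_s > 0)
    l_max[ok] = length * config.burst_duration / out.elapsed_s[ok]
    meta = {
        "burst_mu": dist.mu,
        "burst_sigma": dist.sigma,
        "burst_duration_s": config.burst_duration,
        "pass_length_m": length,
        "seed": config.seed,
        "max_timesteps": config.max_timesteps,
        **{k: v for k, v in field.meta.items() if np.isscalar(v)},
    }
    return PassageResult(model="ibm", outcomes=out.outcomes, moves=out.moves,
                         spawn_j=spawn_j, burst_speed_ms=burst,
                         elapsed_s=out.elapsed_s, ascent_time_s=ascent,
                         l_max_m=l_max, meta=meta)


class IBMPassageModel:
    """Object-style wrapper binding a velocity field and a speed distribution."""

    def __init__(self, field: VelocityField, dist: BurstSpeedDistribution,
                 config: IBMConfig | None = None):
        self.field = field
        self.dist = dist
        self.config = config or IBMConfig()

    def run(self, seed: int | None = None) -> PassageResult:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        return run_ibm(self.field, self.dist, cfg)
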