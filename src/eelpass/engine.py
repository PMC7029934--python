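"""Vectorised movement engine shared by the CA and individual-based models.

Both models move agents on the raster with identical mechanics; they differ
only in how a neighbouring cell qualifies as a destination:

* CA: the cell's *class* must be passable (one threshold for the whole
  cohort, in every direction).
* IBM: the cell must be wet, and for upstream or cross-stream moves the
  agent's own burst speed must exceed the water speed at the destination
  centroid (per-agent passability); downstream (fall-back) moves only
  require water.

Movement per move: the first-order Moore neighbourhood is split into
upstream (3 cells), cross-stream (2) and downstream (3) groups; the agent
draws a destination uniformly at random from the highest-priority non-empty
group — upstream first in normal mode, downstream first in fall-back mode.
An agent whose groups are all empty holds its cell (the move still counts).
An agent making no more than ``stuck_threshold`` cells of net upstream
progress over a trailing window of ``stuck_window`` moves becomes stuck and
falls back for exactly ``fallback_moves`` moves, after which the window
buffer resets; while falling back, stuck assessment is suspended.

Agents are independent, so the engine advances the whole cohort one timestep
at a time with array operations. One global generator is seeded once; each
timestep consumes one uniform draw per active agent, in agent-index order.
This makes a run bit-reproducible for a given seed and makes the simulated
trajectory prefix identical across different ``max_timesteps`` budgets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .results import ACTIVE, EXHAUSTED, PASSED, TIMED_OUT

__all__ = ["EngineOutput", "simulate_cohort", "spawn_edge_cells"]

# Canonical offset order = normal-mode priority: upstream, cross, downstream.
# Upstream is -i (toward the success line at row 0).
OFFSETS = np.array([(-1, -1), (-1, 0), (-1, 1),
                    (0, -1), (0, 1),
                    (1, -1), (1, 0), (1, 1)], dtype=np.int64)
OFF_I = OFFSETS[:, 0]
OFF_J = OFFSETS[:, 1]
NORMAL_ORDER = np.arange(8, dtype=np.int64)
FALLBACK_ORDER = np.array([5, 6, 7, 3, 4, 0, 1, 2], dtype=np.int64)
# group sizes in priority order: 3 (primary), 2 (cross), 3 (tertiary)
_G0, _G1 = 3, 5


@dataclass
class EngineOutput:
    outcomes: np.ndarray     # int8 outcome codes
    moves: np.ndarray        # moves made per agent
    elapsed_s: np.ndarray    # accumulated swim time (all zeros for CA)
    final_i: np.ndarray
    final_j: np.ndarray
    timesteps_run: int


def spawn_edge_cells(wet_edge: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw n spawn columns uniformly (with replacement) from wetted edge cells."""
    js = np.flatnonzero(wet_edge)
    if js.size == 0:
        raise ValueError("downstream edge is entirely boundary; nowhere to spawn")
    return js[rng.integers(0, js.size, size=n)]


def simulate_cohort(
    *,
    wet: np.ndarray,
    spawn_j: np.ndarray,
    rng: np.random.Generator,
    max_timesteps: int,
    stuck_window: int,
    stuck_threshold: int,
    fallback_moves: int,
    static_passable: np.ndarray | None = None,
    speed: np.ndarray | None = None,
    burst: np.ndarray | None = None,
    cell_size: float = 5.0e-4,
    burst_duration: float | None = None,
    diagonal_factor: float = math.sqrt(2.0),
    fallback_time_mode: str = "assisted",
    stuck_assessment: str = "rolling",
) -> EngineOutput:
    """Advance a cohort of independent agents until success, failure or budget.

    Exactly one of ``static_passable`` (CA) or ``speed`` + ``burst`` (IBM)
    must be given. Agents spawn on row ``n - 1`` at columns ``spawn_j`` and
    succeed on reaching row 0.
    """
    ca_mode = static_passable is not None
    if ca_mode == (speed is not None):
        raise ValueError("give either static_passable (CA) or speed+burst (IBM)")
    if not ca_mode and (burst is None or burst_duration is None):
        raise ValueError("IBM mode requires burst speeds and a burst duration")
    if stuck_assessment not in ("rolling", "block"):
        raise ValueError("stuck_assessment must be 'rolling' or 'block'")
    n_rows, n_cols = wet.shape
    n = spawn_j.size

    # padded lookups; the border ring is dry/impassable/infinitely fast
    wet_pad = np.zeros((n_rows + 2, n_cols + 2), dtype=bool)
    wet_pad[1:-1, 1:-1] = wet
    if ca_mode:
        pass_pad = np.zeros_like(wet_pad)
        pass_pad[1:-1, 1:-1] = static_passable
    else:
        speed_pad = np.full((n_rows + 2, n_cols + 2), np.inf)
        speed_pad[1:-1, 1:-1] = np.where(np.isnan(speed), np.inf, speed)

    pos_i = np.full(n, n_rows - 1, dtype=np.int64)
    pos_j = spawn_j.astype(np.int64).copy()
    outcomes = np.full(n, ACTIVE, dtype=np.int8)
    moves = np.zeros(n, dtype=np.int64)
    elapsed = np.zeros(n, dtype=float)
    fb_mode = np.zeros(n, dtype=bool)
    fb_rem = np.zeros(n, dtype=np.int64)

    # trailing window of streamwise positions: stuck_window + 1 entries suffice
    wd = stuck_window + 1
    hist = np.zeros((n, wd), dtype=np.int64)
    hist[:, 0] = pos_i
    hcount = np.ones(n, dtype=np.int64)

    # agents already spawned on the success line (degenerate 1-row grids are
    # excluded by GridSpec, but keep the engine total)
    at_top = pos_i == 0
    outcomes[at_top] = PASSED

    t = 0
    while t < max_timesteps:
        act = np.flatnonzero(outcomes == ACTIVE)
        if act.size == 0:
            break
        t += 1
        k = act.size
        pi = pos_i[act]
        pj = pos_j[act]
        ni = pi[:, None] + OFF_I[None, :] + 1   # +1: pad offset
        nj = pj[:, None] + OFF_J[None, :] + 1

        if ca_mode:
            viab = pass_pad[ni, nj]
        else:
            wetn = wet_pad[ni, nj]
            swimmable = speed_pad[ni, nj] < burst[act][:, None]
            downstream = (OFF_I > 0)[None, :]
            viab = wetn & (swimmable | downstream)

        fb = fb_mode[act]
        order = np.where(fb[:, None], FALLBACK_ORDER[None, :],
                         NORMAL_ORDER[None, :])
        vp = np.take_along_axis(viab, order, axis=1)
        c0 = vp[:, :_G0].sum(axis=1)
        c1 = vp[:, _G0:_G1].sum(axis=1)
        c2 = vp[:, _G1:].sum(axis=1)
        grp = np.where(c0 > 0, 0, np.where(c1 > 0, 1, np.where(c2 > 0, 2, -1)))
        cnt = np.select([grp == 0, grp == 1, grp == 2], [c0, c1, c2], default=0)

        u = rng.random(k)   # one draw per active agent, agent-index order
        sel = np.minimum((u * cnt).astype(np.int64), np.maximum(cnt - 1, 0))
        cs = np.cumsum(vp, axis=1)
        base = np.select([grp == 0, grp == 1, grp == 2],
                         [np.zeros(k, dtype=np.int64), c0, c0 + c1], default=0)
        target = base + sel + 1
        slot_p = np.argmax(cs == target[:, None], axis=1)
        slot = np.take_along_axis(order, slot_p[:, None], axis=1)[:, 0]

        movers = grp >= 0
        di = np.where(movers, OFF_I[slot], 0)
        dj = np.where(movers, OFF_J[slot], 0)
        new_i = pi + di
        new_j = pj + dj

        if not ca_mode:
            u_dest = speed_pad[new_i + 1, new_j + 1]
            v = burst[act]
            rel = np.where(di > 0, v + u_dest, v - u_dest)
            dist = cell_size * np.where((di != 0) & (dj != 0),
                                        diagonal_factor, 1.0)
            dt = np.zeros(k)
            safe = movers & (rel > 0)
            dt[safe] = dist[safe] / rel[safe]
            if fallback_time_mode == "free":
                dt[di > 0] = 0.0
            elapsed[act] += dt

        pos_i[act] = new_i
        pos_j[act] = new_j
        moves[act] += 1

        idx = hcount[act] % wd
        hist[act, idx] = new_i
        hcount[act] += 1

        passed = new_i == 0
        outcomes[act[passed]] = PASSED
        if not ca_mode:
            exhausted = ~passed & (elapsed[act] > burst_duration)
            outcomes[act[exhausted]] = EXHAUSTED

        # fall-back countdown (this move consumed one fall-back move)
        fb_idx = act[fb]
        fb_rem[fb_idx] -= 1
        done = fb_idx[fb_rem[fb_idx] <= 0]
        fb_mode[done] = False
        fb_rem[done] = 0
        hist[done, 0] = pos_i[done]   # window buffer resets on exit
        hcount[done] = 1

        # stuck assessment for normal-mode agents with a full window
        cand = act[~fb & (outcomes[act] == ACTIVE)]
        if cand.size:
            since = hcount[cand] - 1   # moves since last buffer reset
            full = since >= stuck_window
            if stuck_assessment == "block":
                full &= since % stuck_window == 0
            cand = cand[full]
            if cand.size:
                prev = hist[cand, (hcount[cand] - 1 - stuck_window) % wd]
                progress = prev - pos_i[cand]   # cells gained toward row 0
                stuck = cand[progress <= stuck_threshold]
                fb_mode[stuck] = True
                fb_rem[stuck] = fallback_moves

    outcomes[outcomes == ACTIVE] = TIMED_OUT
    return EngineOutput(outcomes=outcomes, moves=moves, elapsed_s=elapsed,
                        final_i=pos_i, final_j=pos_j, timesteps_run=t)
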