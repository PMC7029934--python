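"""Passage-efficiency arithmetic, cross-scenario aggregation and design charts.

Observed passage efficiency is successes divided by attempts, in percent.
Counts may be fractional because field studies report trial means (e.g.
14.1 +/- 4.86 attempts). Attempts logged against the centre of a pass with no
corresponding successes can optionally be reallocated half-and-half to the
two stud families, which dilutes both families' efficiencies.

Design charts interrogate the per-agent distribution of maximum ascendable
pass length L_max from an individual-based run: the pass length achievable at
a target efficiency e% is the largest length that at least e% of agents can
ascend — the (1 - e/100) quantile of the L_max distribution with failed
agents contributing L_max = 0 (no pass length gets a failed agent across, so
targets above the raw pass rate correctly map to zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .results import PassageResult

__all__ = ["AttemptCounts", "DesignPoint", "efficiency_from_counts",
           "design_chart", "quantile_pass_length", "unit_discharge",
           "weir_entrance_depth"]


@dataclass(frozen=True)
class AttemptCounts:
    """Observed ascent attempts and successes (fractional trial means allowed)."""

    successes: float
    attempts: float
    unassigned_attempts: float = 0.0

    def __post_init__(self) -> None:
        if min(self.successes, self.attempts, self.unassigned_attempts) < 0:
            raise ValueError("counts must be non-negative")
        if self.successes > self.attempts + self.unassigned_attempts:
            raise ValueError("successes exceed attempts plus unassigned share")


def efficiency_from_counts(c: AttemptCounts, reallocate: bool = False) -> float:
    """Passage efficiency in percent from observed counts.

    With ``reallocate``, half of the unassigned (centre) attempts are added
    to the denominator — the even split between the two stud families.
    """
    if not c.attempts > 0:
        raise ValueError("attempts must be positive")
    denom = c.attempts + (c.unassigned_attempts / 2.0 if reallocate else 0.0)
    return 100.0 * c.successes / denom


@dataclass(frozen=True)
class DesignPoint:
    """One row of a design chart."""

    angle_deg: float
    q_m2s: float
    elver_length_m: float
    target_pct: float
    pass_length_m: float

    def __post_init__(self) -> None:
        if not 0 <= self.target_pct <= 100:
            raise ValueError("target efficiency must lie in [0, 100]")


def quantile_pass_length(l_max: np.ndarray, target_pct: float) -> float:
    """Largest pass length that at least ``target_pct`` % of agents can ascend.

    Equivalently the (1 - target/100) upper quantile of the L_max sample:
    sort descending and take the ceil(n * target / 100)-th value.
    """
    if not 0 < target_pct <= 100:
        raise ValueError("target_pct must lie in (0, 100]")
    arr = np.sort(np.asarray(l_max, dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("empty L_max sample")
    k = math.ceil(arr.size * target_pct / 100.0)
    return float(arr[k - 1])


def design_chart(results: Iterable[PassageResult],
                 targets: Iterable[float] = (40.0, 60.0, 80.0)) -> pd.DataFrame:
    """Long-format design-chart table from a collection of IBM results.

    Each result must carry per-agent ``l_max_m`` and scenario metadata
    (``angle_deg``, ``q_m2s``, ``elver_length_m``). Returns one row per
    (scenario, target efficiency) with the achievable pass length.
    """
    targets = sorted(float(t) for t in targets)
    rows: list[DesignPoint] = []
    n_results = 0
    for res in results:
        n_results += 1
        if res.l_max_m is None:
            raise ValueError("design_chart needs results with per-agent L_max "
                             "(individual-based runs)")
        for t in targets:
            rows.append(DesignPoint(
                angle_deg=float(res.meta.get("angle_deg", float("nan"))),
                q_m2s=float(res.meta.get("q_m2s", float("nan"))),
                elver_length_m=float(res.meta.get("elver_length_m", float("nan"))),
                target_pct=t,
                pass_length_m=quantile_pass_length(res.l_max_m, t),
            ))
    if n_results == 0:
        raise ValueError("empty result collection")
    return pd.DataFrame([r.__dict__ for r in rows])


def unit_discharge(mean_velocity: float, depth: float) -> float:
    """Discharge per unit channel width q = U * h (m^2/s)."""
    if mean_velocity < 0 or depth < 0:
        raise ValueError("inputs must be non-negative")
    return mean_velocity * depth


def weir_entrance_depth(q: float, alpha: float, crest_elevation: float) -> float:
    """Flow depth at the pass entrance from the weir rating q = alpha (y_b + h)^1.5.

    Inverts to h = (q / alpha)^(2/3) - y_b. A negative result means the pass
    entrance sits above the water line for this discharge; it is returned
    as-is with a warning so the caller can flag the design.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    h = (q / alpha) ** (2.0 / 3.0) - crest_elevation
    if h < 0:
        warnings.warn("pass entrance above water line (negative entrance depth)",
                      stacklevel=2)
    return h


def plot_design_chart(table: pd.DataFrame, elver_length_m: float, ax=None):
    """Pass length against installation angle, one curve per (q, target)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = table[np.isclose(table["elver_length_m"], elver_length_m)]
    for (q, t), grp in sub.groupby(["q_m2s", "target_pct"]):
        grp = grp.sort_values("angle_deg")
        ax.plot(grp["angle_deg"], grp["pass_length_m"], marker="o",
                label=f"q={q:g} m$^2$/s, {t:g}%")
    ax.set_xlabel("installation angle (deg)")
    ax.set_ylabel("pass length (m)")
    ax.set_title(f"achievable pass length, elver length {elver_length_m:g} m")
    ax.legend(fontsize=7)
    return ax
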