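"""Per-agent outcomes and summary statistics of one passage simulation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["OUTCOME_LABELS", "PassageResult"]

# outcome codes shared by the CA and IBM engines
ACTIVE, PASSED, TIMED_OUT, EXHAUSTED = 0, 1, 2, 3
OUTCOME_LABELS = {ACTIVE: "active", PASSED: "passed",
                  TIMED_OUT: "timed_out", EXHAUSTED: "exhausted"}


@dataclass
class PassageResult:
    """Outcome of simulating a cohort of agents through one scenario.

    ``efficiency`` is the percentage of agents that reached the upstream edge.
    For individual-based runs, ``ascent_time_s`` holds the swim time of passed
    agents (NaN otherwise) and ``l_max_m`` the maximum pass length each agent
    could have ascended within the burst budget (0 for failed agents), the
    quantity design charts interrogate.
    """

    model: str                       # "ca" or "ibm"
    outcomes: np.ndarray             # int8 outcome codes, one per agent
    moves: np.ndarray                # moves made per agent
    spawn_j: np.ndarray              # spanwise spawn cell per agent
    burst_speed_ms: np.ndarray | None = None   # IBM only
    elapsed_s: np.ndarray | None = None        # IBM only: total swim time
    ascent_time_s: np.ndarray | None = None    # IBM only: NaN if not passed
    l_max_m: np.ndarray | None = None          # IBM only: 0 if not passed
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_agents(self) -> int:
        return int(self.outcomes.size)

    @property
    def n_passed(self) -> int:
        return int(np.count_nonzero(self.outcomes == PASSED))

    @property
    def efficiency(self) -> float:
        """Passage efficiency in percent, 100 * n_passed / n_agents."""
        return 100.0 * self.n_passed / self.n_agents

    def to_frame(self) -> pd.DataFrame:
        """Per-agent long-format table."""
        data = {
            "agent": np.arange(self.n_agents),
            "outcome": [OUTCOME_LABELS[int(c)] for c in self.outcomes],
            "moves": self.moves,
            "spawn_j": self.spawn_j,
        }
        if self.burst_speed_ms is not None:
            data["burst_speed_ms"] = self.burst_speed_ms
        if self.elapsed_s is not None:
            data["elapsed_s"] = self.elapsed_s
        if self.ascent_time_s is not None:
            data["ascent_time_s"] = self.ascent_time_s
        if self.l_max_m is not None:
            data["l_max_m"] = self.l_max_m
        return pd.DataFrame(data)

    def to_payload(self) -> dict:
        """JSON-serialisable summary (stable key order, no timestamps)."""
        payload = {
            "model": self.model,
            "n_agents": self.n_agents,
            "n_passed": self.n_passed,
            "efficiency_pct": round(self.efficiency, 1),
            "outcome_counts": {
                OUTCOME_LABELS[code]: int(np.count_nonzero(self.outcomes == code))
                for code in sorted(OUTCOME_LABELS)
            },
            "meta": {k: self.meta[k] for k in sorted(self.meta)},
        }
        if self.ascent_time_s is not None:
            passed_t = self.ascent_time_s[np.isfinite(self.ascent_time_s)]
            payload["ascent_time_s"] = {
                "median": float(np.median(passed_t)) if passed_t.size else None,
                "p10": float(np.percentile(passed_t, 10)) if passed_t.size else None,
                "p90": float(np.percentile(passed_t, 90)) if passed_t.size else None,
            }
        return payload

    def to_json(self) -> str:
        return json.dumps(self.to_payload(), sort_keys=True, indent=2)

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            f"{self.model.upper()} passage simulation",
            "-" * 40,
            f"agents             {self.n_agents}",
            f"passed             {self.n_passed}",
            f"efficiency         {self.efficiency:.1f}%",
        ]
        for code in (TIMED_OUT, EXHAUSTED):
            n = int(np.count_nonzero(self.outcomes == code))
            if n:
                lines.append(f"{OUTCOME_LABELS[code]:<18} {n}")
        if self.ascent_time_s is not None and self.n_passed:
            t = self.ascent_time_s[np.isfinite(self.ascent_time_s)]
            lines.append(f"median ascent time {np.median(t):.2f} s")
        for key in sorted(self.meta):
            lines.append(f"{key:<18} {self.meta[key]}")
        return "\n".join(lines)
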