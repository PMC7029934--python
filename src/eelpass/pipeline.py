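"""End-to-end orchestration: field -> classification -> model -> summaries.

A run is fully described by a :class:`RunConfig` (loadable from a TOML file
with ``[scenario]``, ``[model]`` and ``[paths]`` tables, every key
overridable). Identical config + seed gives byte-identical CSV/JSON artifacts:
outputs embed the resolved configuration and seed but no timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import classify, flowfield, swim, synthetic
from .ca import CAConfig, run_ca
from .ibm import IBMConfig, run_ibm
from .results import PassageResult

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "sweep"]

log = logging.getLogger("eelpass")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    # scenario
    angle_deg: float = 11.0
    q_m2s: float = 3.33e-3
    pass_length_m: float = 1.25
    pass_width_m: float = 4.5e-2
    cell_size_m: float = 5.0e-4
    elver_length_m: float = 0.07
    percentile: int = 50          # CA threshold percentile (10/50/90)
    # model
    model: str = "ibm"            # "ca" or "ibm"
    n_agents: int = 1000
    max_timesteps: int = 10_000
    stuck_window: int = 20
    stuck_threshold: int = 2
    fallback_moves: int = 30
    burst_duration_s: float = 20.0
    seed: int = 0
    # paths; grid_in empty -> synthesise the field
    grid_in: str = ""
    speeds_table: str = ""        # empty -> packaged synthetic table
    plot: bool = False

    def ca_config(self) -> CAConfig:
        return CAConfig(n_agents=self.n_agents, max_timesteps=self.max_timesteps,
                        stuck_window=self.stuck_window,
                        stuck_threshold=self.stuck_threshold,
                        fallback_moves=self.fallback_moves, seed=self.seed)

    def ibm_config(self) -> IBMConfig:
        return IBMConfig(n_agents=self.n_agents, max_timesteps=self.max_timesteps,
                         stuck_window=self.stuck_window,
                         stuck_threshold=self.stuck_threshold,
                         fallback_moves=self.fallback_moves, seed=self.seed,
                         burst_duration=self.burst_duration_s)


def load_run_config(path) -> RunConfig:
    """Read a TOML config file; tables are flattened into RunConfig fields."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    flat: dict = {}
    for value in raw.values():
        if isinstance(value, dict):
            flat.update(value)
        # top-level scalars are ignored; tables are the interface
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**flat)


def _field_for(config: RunConfig) -> flowfield.VelocityField:
    if config.grid_in:
        return flowfield.read_grid(config.grid_in)
    scenario = synthetic.FlowScenario(
        angle_deg=config.angle_deg, q_m2s=config.q_m2s,
        length=config.pass_length_m, width=config.pass_width_m,
        seed=config.seed)
    grid = flowfield.GridSpec(
        n_streamwise=max(2, round(config.pass_length_m / config.cell_size_m)),
        n_spanwise=max(1, round(config.pass_width_m / config.cell_size_m)),
        cell_size=config.cell_size_m)
    vf, _ = synthetic.generate_field(scenario, grid=grid)
    return vf


def _speed_table(config: RunConfig) -> list[swim.SpeedQuantiles]:
    if config.speeds_table:
        return swim.load_quantile_table(config.speeds_table)
    return swim.synthetic_quantile_table()


def run_scenario(config: RunConfig) -> PassageResult:
    """Field -> (classify) -> model, without touching the filesystem."""
    t0 = time.perf_counter()
    field = _field_for(config)
    log.info("field ready (%dx%d) in %.2fs", *field.grid.shape,
             time.perf_counter() - t0)
    table = _speed_table(config)
    if config.model == "ca":
        threshold = swim.quantiles_for_length(table, config.elver_length_m,
                                              config.percentile)
        cf = classify.classify_field(field, threshold)
        result = run_ca(cf, config.ca_config())
    elif config.model == "ibm":
        dist = swim.distribution_for_length(table, config.elver_length_m)
        result = run_ibm(field, dist, config.ibm_config())
    else:
        raise ValueError(f"unknown model '{config.model}'")
    result.meta["elver_length_m"] = config.elver_length_m
    log.info("%s run done: efficiency %.1f%%", config.model, result.efficiency)
    return result


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run one scenario end-to-end and write the artifact bundle.

    Writes the (possibly synthesised) velocity grid, the per-agent CSV and a
    summary JSON embedding the resolved config. Returns the artifact paths
    plus the in-memory result.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        field = _field_for(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'field': {exc}") from exc
    grid_path = outdir / "velocity.grid"
    flowfield.write_grid(field, grid_path)
    try:
        result = run_scenario(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'model': {exc}") from exc
    agents_path = outdir / "agents.csv"
    result.to_frame().to_csv(agents_path, index=False)
    payload = result.to_payload()
    payload["config"] = {k: v for k, v in sorted(asdict(config).items())}
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(payload, sort_keys=True, indent=2))
    artifacts = {"grid": grid_path, "agents": agents_path,
                 "summary": summary_path, "result": result}
    if config.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .plotting import plot_classified_map

        table = _speed_table(config)
        threshold = swim.quantiles_for_length(table, config.elver_length_m,
                                              config.percentile)
        cf = classify.classify_field(field, threshold)
        ax = plot_classified_map(cf)
        fig_path = outdir / "classified_map.png"
        ax.figure.savefig(fig_path, dpi=150)
        plt.close(ax.figure)
        artifacts["map"] = fig_path
    return artifacts


def sweep(config: RunConfig, angles, discharges, elver_lengths
          ) -> tuple[list[PassageResult], "object"]:
    """Run the scenario grid |angles| x |discharges| x |lengths|.

    Returns the per-scenario results (inputs to :func:`summaries.design_chart`)
    and a tidy efficiency table. Failures in individual scenarios are
    collected and re-raised together so a long sweep reports every problem.
    """
    import pandas as pd

    from dataclasses import replace

    results: list[PassageResult] = []
    rows = []
    failures = []
    for angle in angles:
        for q in discharges:
            for length in elver_lengths:
                cfg = replace(config, angle_deg=float(angle), q_m2s=float(q),
                              elver_length_m=float(length))
                try:
                    res = run_scenario(cfg)
                except Exception as exc:   # collected partial-failure report
                    failures.append((angle, q, length, exc))
                    continue
                results.append(res)
                rows.append({"angle_deg": angle, "q_m2s": q,
                             "elver_length_m": length, "model": cfg.model,
                             "efficiency_pct": round(res.efficiency, 1)})
    if failures:
        detail = "; ".join(f"(theta={a}, q={q}, L={l}): {e}"
                           for a, q, l, e in failures)
        raise RuntimeError(f"{len(failures)} sweep scenario(s) failed: {detail}")
    return results, pd.DataFrame(rows)
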