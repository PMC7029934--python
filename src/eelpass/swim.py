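"""Burst-swimming-speed model for elvers.

Swimming-performance datasets typically report, per fish length, the 10th,
50th and 90th percentile burst swimming speed — the fastest speed a fish can
sustain anaerobically, conventionally budgeted at 20 s. The individual-based
model needs a full distribution to draw heterogeneous agents from, so the
quantile triple is converted to a lognormal:

    mu    = ln(q50)                      (the median pins the location)
    sigma = (ln q90 - ln q10) / (2 z90)  with z90 = Phi^-1(0.9) = 1.28155

Three quantiles over-determine the two-parameter lognormal; pinning mu to the
median and averaging the two one-sided scale estimates is exact for
log-symmetric triples and the least-squares compromise otherwise.

Quantile tables are user-supplied delimited text (columns ``length_m, q10,
q50, q90, season, temperature_C``). The table shipped with the package is
synthetic — placeholder values proportional to body length, clearly
non-biological — and exists only so the pipeline runs out of the box.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Z90",
    "SpeedQuantiles",
    "BurstSpeedDistribution",
    "EnduranceBudget",
    "fit_lognormal",
    "sample_speeds",
    "quantiles_for_length",
    "distribution_for_length",
    "load_quantile_table",
    "synthetic_quantile_table",
]

#: standard normal 90th percentile, z_{0.9}
Z90 = 1.2815515655446004


@dataclass(frozen=True)
class SpeedQuantiles:
    """10th/50th/90th percentile burst speed (m/s) for one elver length."""

    elver_length: float   # body length, m
    q10: float
    q50: float
    q90: float
    season: str = "spring"
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.q10 <= self.q50 <= self.q90):
            raise ValueError(
                f"quantiles must satisfy 0 < q10 <= q50 <= q90, "
                f"got ({self.q10}, {self.q50}, {self.q90})"
            )


@dataclass(frozen=True)
class BurstSpeedDistribution:
    """Lognormal burst-speed distribution in log-space parameters."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def quantile(self, p: float | np.ndarray) -> float | np.ndarray:
        from scipy.stats import norm

        return np.exp(self.mu + self.sigma * norm.ppf(p))

    def cdf(self, v: float | np.ndarray) -> float | np.ndarray:
        """P(burst speed <= v)."""
        from scipy.stats import norm

        v = np.asarray(v, dtype=float)
        out = np.where(v <= 0, 0.0,
                       norm.cdf((np.log(np.maximum(v, 1e-300)) - self.mu)
                                / self.sigma) if self.sigma > 0
                       else (v >= np.exp(self.mu)).astype(float))
        return out if out.ndim else float(out)

    @property
    def fitted_quantiles(self) -> tuple[float, float, float]:
        """(q10, q50, q90) implied by the fitted parameters, for inspection."""
        return (float(np.exp(self.mu - self.sigma * Z90)),
                self.median,
                float(np.exp(self.mu + self.sigma * Z90)))


@dataclass(frozen=True)
class EnduranceBudget:
    """Total time a fish can sustain burst swimming; 20 s by convention."""

    burst_duration: float = 20.0

    def __post_init__(self) -> None:
        if not self.burst_duration > 0:
            raise ValueError("burst_duration must be positive")


def fit_lognormal(q: SpeedQuantiles) -> BurstSpeedDistribution:
    """Fit a lognormal to a quantile triple by inverting its quantile function.

    mu is pinned to the median; sigma is the mean of the upper and lower
    one-sided estimates, ((ln q90 - ln q50) + (ln q50 - ln q10)) / (2 z90),
    which collapses to (ln q90 - ln q10) / (2 z90).
    """
    mu = float(np.log(q.q50))
    sigma = float((np.log(q.q90) - np.log(q.q10)) / (2.0 * Z90))
    return BurstSpeedDistribution(mu=mu, sigma=sigma)


def sample_speeds(dist: BurstSpeedDistribution, n: int,
                  seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` independent burst speeds; reproducible given a seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(rng.normal(dist.mu, dist.sigma, size=n))


def quantiles_for_length(table: list[SpeedQuantiles], length: float,
                         percentile: int) -> float:
    """Linearly interpolate a tabulated percentile speed at an elver length.

    No extrapolation: lengths outside the tabulated range raise.
    """
    if percentile not in (10, 50, 90):
        raise ValueError("percentile must be 10, 50 or 90")
    rows = sorted(table, key=lambda r: r.elver_length)
    lengths = np.array([r.elver_length for r in rows])
    if not (lengths[0] <= length <= lengths[-1]):
        raise ValueError(
            f"length {length} m outside tabulated range "
            f"[{lengths[0]}, {lengths[-1]}] m"
        )
    values = np.array([getattr(r, f"q{percentile}") for r in rows])
    return float(np.interp(length, lengths, values))


def distribution_for_length(table: list[SpeedQuantiles], length: float
                            ) -> BurstSpeedDistribution:
    """Interpolate the quantile triple at ``length`` and fit a lognormal."""
    triple = SpeedQuantiles(
        elver_length=length,
        q10=quantiles_for_length(table, length, 10),
        q50=quantiles_for_length(table, length, 50),
        q90=quantiles_for_length(table, length, 90),
    )
    return fit_lognormal(triple)


def load_quantile_table(path) -> list[SpeedQuantiles]:
    """Read a delimited quantile table (length_m, q10, q50, q90, ...)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"length_m", "q10", "q50", "q90"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quantile table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(SpeedQuantiles(
            elver_length=float(rec.length_m),
            q10=float(rec.q10), q50=float(rec.q50), q90=float(rec.q90),
            season=str(getattr(rec, "season", "spring")),
            temperature_c=float(rec.temperature_C)
            if hasattr(rec, "temperature_C") else None,
        ))
    return rows


def synthetic_quantile_table() -> list[SpeedQuantiles]:
    """The packaged *synthetic* placeholder table (non-biological values).

    Median speed is ~5 body lengths per second with fixed q10/q50 = 0.6 and
    q90/q50 = 1.5 ratios; replace with measured data for any real assessment.
    """
    ref = importlib.resources.files("eelpass.data") / "swim_quantiles_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return load_quantile_table(path)
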