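"""Gridded near-bed velocity and depth fields for studded eel passes.

The ascent domain is a regular raster. Streamwise index ``i`` runs from 0 at
the *upstream* edge (the success line for an ascending elver) to ``n - 1`` at
the *downstream* edge, where agents enter the pass; water flows in the +i
direction, elvers swim in -i. Spanwise index ``j`` runs 0..m-1 across the
pass. Cell centroids sit at ``((i + 0.5) * cell_size, (j + 0.5) * cell_size)``.

Velocity is stored as the scalar magnitude of the time-averaged flow sampled
on a plane a few millimetres above the tile bed (default 3 mm) — the height
at which near-bed speeds peak and at which an elver's body sits. Cells that
contain no water (stud cross-sections, walls) carry NaN and are tracked by
the ``nodata`` mask.

Grid files are plain delimited text: ``#``-prefixed ``key = value`` header
lines followed by a row-major body (one line per streamwise index ``i``),
with a negative sentinel (-1) standing in for nodata cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "VelocityField",
    "DepthField",
    "HydraulicSummary",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "read_depth",
    "write_depth",
    "regrid_linear",
    "temporal_average",
    "mirror_spanwise",
    "hydraulic_summary",
]

NODATA_SENTINEL = -1.0


class GridFormatError(ValueError):
    """Raised when a grid file's header or body cannot be parsed."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster over the pass bed.

    Parameters
    ----------
    n_streamwise : int
        Number of cells along the ascent axis (>= 2).
    n_spanwise : int
        Number of cells across the pass (>= 1).
    cell_size : float
        Cell edge length in metres; default 0.5 mm.
    """

    n_streamwise: int
    n_spanwise: int
    cell_size: float = 5.0e-4

    def __post_init__(self) -> None:
        if self.n_streamwise < 2:
            raise ValueError("n_streamwise must be >= 2")
        if self.n_spanwise < 1:
            raise ValueError("n_spanwise must be >= 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_streamwise, self.n_spanwise)

    @property
    def length(self) -> float:
        """Streamwise extent of the raster in metres."""
        return self.n_streamwise * self.cell_size

    @property
    def width(self) -> float:
        """Spanwise extent of the raster in metres."""
        return self.n_spanwise * self.cell_size

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (x, z) of cell-centroid coordinates, shape ``shape``."""
        x = (np.arange(self.n_streamwise) + 0.5) * self.cell_size
        z = (np.arange(self.n_spanwise) + 0.5) * self.cell_size
        return np.meshgrid(x, z, indexing="ij")


def _validate_raster(grid: GridSpec, values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"{name} shape {arr.shape} does not match grid {grid.shape}")
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError(f"{name} must be non-negative where defined")
    return arr


@dataclass
class VelocityField:
    """Time-averaged near-bed speed magnitude on a regular grid.

    ``speed`` holds m/s values with NaN marking nodata (dry) cells.
    ``meta`` carries scenario provenance such as installation angle
    (``angle_deg``), unit discharge (``q_m2s``) and the averaging window.
    """

    grid: GridSpec
    speed: np.ndarray
    sample_height: float = 3.0e-3
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.speed = _validate_raster(self.grid, self.speed, "speed")
        if not self.sample_height > 0:
            raise ValueError("sample_height must be positive")

    @property
    def nodata(self) -> np.ndarray:
        """Boolean mask of cells containing no water."""
        return np.isnan(self.speed)

    @property
    def wetted_mean(self) -> float:
        """Spatial mean speed over wetted cells (m/s)."""
        if np.all(self.nodata):
            raise ValueError("field has no wetted cells")
        return float(np.nanmean(self.speed))


@dataclass
class DepthField:
    """Local water depth (m) on the same raster convention as VelocityField."""

    grid: GridSpec
    depth: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = _validate_raster(self.grid, self.depth, "depth")

    @property
    def nodata(self) -> np.ndarray:
        return np.isnan(self.depth)


# ---------------------------------------------------------------------------
# Delimited-text grid format (shared by velocity, depth and classified grids)
# ---------------------------------------------------------------------------

_META_FLOAT_KEYS = ("angle_deg", "q_m2s", "avg_window_s")


def _write_raster(path, kind: str, grid: GridSpec, body: np.ndarray,
                  extra_header: dict, fmt: str = "%.17g") -> None:
    lines = [
        "# eelpass-grid v1",
        f"# kind = {kind}",
        f"# cell_size_m = {grid.cell_size!r}",
        f"# n_streamwise = {grid.n_streamwise}",
        f"# n_spanwise = {grid.n_spanwise}",
        f"# nodata = {NODATA_SENTINEL:g}",
    ]
    for key, value in extra_header.items():
        lines.append(f"# {key} = {value}")
    buf = io.StringIO()
    out = np.where(np.isnan(body), NODATA_SENTINEL, body)
    np.savetxt(buf, np.atleast_2d(out), fmt=fmt, delimiter="\t")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def _read_raster(path) -> tuple[dict, np.ndarray]:
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    header[key.strip()] = value.strip()
                continue
            body_lines.append((lineno, line))
    for key in ("cell_size_m", "n_streamwise", "n_spanwise", "nodata"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header key '{key}'")
    n = int(header["n_streamwise"])
    m = int(header["n_spanwise"])
    rows = []
    for lineno, line in body_lines:
        values = line.split()
        if len(values) != m:
            raise GridFormatError(
                f"{path}: line {lineno} has {len(values)} columns, header declares {m}"
            )
        try:
            rows.append([float(v) for v in values])
        except ValueError as exc:
            raise GridFormatError(f"{path}: line {lineno}: {exc}") from None
    if len(rows) != n:
        raise GridFormatError(
            f"{path}: body has {len(rows)} rows, header declares {n}"
        )
    body = np.asarray(rows, dtype=float)
    sentinel = float(header["nodata"])
    body[body == sentinel] = np.nan
    return header, body


def write_grid(field: VelocityField, path) -> None:
    """Serialise a velocity field to the delimited-text grid format."""
    extra = {"sample_height_m": repr(field.sample_height), "units": "m s-1"}
    for key in _META_FLOAT_KEYS:
        if key in field.meta:
            extra[key] = repr(float(field.meta[key]))
    _write_raster(path, "velocity", field.grid, field.speed, extra)


def read_grid(path) -> VelocityField:
    """Read a velocity field written by :func:`write_grid`.

    Round-trips bit-exactly on the text representation: values are written
    with 17 significant digits, so write -> read -> write reproduces the file.
    """
    header, body = _read_raster(path)
    grid = GridSpec(int(header["n_streamwise"]), int(header["n_spanwise"]),
                    float(header["cell_size_m"]))
    meta = {k: float(v) for k, v in header.items() if k in _META_FLOAT_KEYS}
    return VelocityField(
        grid=grid,
        speed=body,
        sample_height=float(header.get("sample_height_m", 3.0e-3)),
        meta=meta,
    )


def write_depth(field: DepthField, path) -> None:
    _write_raster(path, "depth", field.grid, field.depth, {"units": "m"})


def read_depth(path) -> DepthField:
    header, body = _read_raster(path)
    grid = GridSpec(int(header["n_streamwise"]), int(header["n_spanwise"]),
                    float(header["cell_size_m"]))
    return DepthField(grid=grid, depth=body)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def regrid_linear(points: np.ndarray, target: GridSpec,
                  sample_height: float = 3.0e-3) -> VelocityField:
    """Linearly interpolate scattered (x, z, speed) samples onto a raster.

    Mimics the resampling of solver output from an irregular mesh onto the
    regular analysis grid: piecewise-linear (barycentric) interpolation on the
    Delaunay triangulation of the samples; grid centroids outside the convex
    hull of the samples become nodata.

    Parameters
    ----------
    points : array, shape (N, 3)
        Columns x (streamwise, m), z (spanwise, m), speed (m/s). N >= 3,
        not all collinear.
    """
    from scipy.interpolate import griddata
    from scipy.spatial import QhullError

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("points must be an (N, 3) array with N >= 3")
    xg, zg = target.centroids()
    try:
        values = griddata(pts[:, :2], pts[:, 2], (xg, zg), method="linear")
    except QhullError as exc:
        raise ValueError(f"sample points are degenerate (collinear?): {exc}") from None
    return VelocityField(grid=target, speed=values, sample_height=sample_height)


def temporal_average(fields: Sequence[VelocityField], times: Sequence[float],
                     window: tuple[float, float]) -> VelocityField:
    """Arithmetic per-cell mean of snapshots whose time lies in ``window``.

    A cell that is nodata in *any* selected snapshot is nodata in the result:
    a sometimes-dry cell has no well-defined time-averaged swimming
    environment.
    """
    if len(fields) != len(times):
        raise ValueError("fields and times must have equal length")
    t0, t1 = window
    selected = [f for f, t in zip(fields, times) if t0 <= t <= t1]
    if not selected:
        raise ValueError(f"window [{t0}, {t1}] selects no snapshots")
    grid = selected[0].grid
    for f in selected[1:]:
        if f.grid != grid:
            raise ValueError("all snapshots must share the same GridSpec")
    stack = np.stack([f.speed for f in selected])
    mean = stack.mean(axis=0)  # plain mean: any NaN propagates
    return VelocityField(grid=grid, speed=mean,
                         sample_height=selected[0].sample_height,
                         meta={**selected[0].meta, "avg_window_s": t1 - t0})


def mirror_spanwise(field: VelocityField) -> VelocityField:
    """Reflect the field about its spanwise edge, doubling the width.

    Used to rebuild a full-width pass from a half-domain computed with a
    symmetry boundary: output column ``j`` equals column ``2 m - 1 - j``.
    """
    speed = np.concatenate([field.speed, field.speed[:, ::-1]], axis=1)
    grid = GridSpec(field.grid.n_streamwise, 2 * field.grid.n_spanwise,
                    field.grid.cell_size)
    return VelocityField(grid=grid, speed=speed,
                         sample_height=field.sample_height,
                         meta=dict(field.meta))


@dataclass(frozen=True)
class HydraulicSummary:
    """Bulk hydraulic characterisation of a (velocity, depth) field pair."""

    mean_speed: float       # U, spatial mean over wetted cells (m/s)
    mean_depth: float       # h-bar (m)
    re_depth: float         # U * h / nu
    re_stud: float          # U * d / nu
    unit_discharge: float   # q-hat = U * h-bar (m^2/s)


def hydraulic_summary(field: VelocityField, depth: DepthField, nu: float,
                      stud_diameter: float) -> HydraulicSummary:
    """Bulk means and Reynolds numbers for a near-bed field.

    ``re_depth`` uses the mean flow depth as length scale, ``re_stud`` the
    caller-supplied stud diameter (the appropriate diameter — base, top or
    mean — is a modelling choice left to the caller).
    """
    if not nu > 0:
        raise ValueError("kinematic viscosity must be positive")
    if np.all(field.nodata):
        raise ValueError("velocity field is entirely nodata")
    u = float(np.nanmean(field.speed))
    h = float(np.nanmean(depth.depth))
    return HydraulicSummary(
        mean_speed=u,
        mean_depth=h,
        re_depth=u * h / nu,
        re_stud=u * stud_diameter / nu,
        unit_discharge=u * h,
    )
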