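"""Threshold classification of velocity fields and passability analysis.

A cell is *passable* for an elver when the local time-averaged speed is
strictly less than the elver's burst swimming speed, *impassable* when the
speed is greater than or equal to it, and *boundary* when the cell contains
no water (stud or wall). Whether a whole pass is ascendable is a connectivity
question: does a Moore-connected (8-neighbour) chain of passable cells link
the downstream entry edge to the upstream exit edge? The 8-neighbour
adjacency is deliberately the same as the movement rule of the automata, so
"a path exists" is equivalent to "an automaton could in principle ascend".
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .flowfield import GridSpec, VelocityField, _read_raster, _write_raster

__all__ = [
    "PASSABLE",
    "IMPASSABLE",
    "BOUNDARY",
    "ClassifiedField",
    "AreaFractions",
    "PathResult",
    "classify_field",
    "area_fractions",
    "has_continuous_path",
    "read_classified",
    "write_classified",
]

PASSABLE = 0
IMPASSABLE = 1
BOUNDARY = 2

# full 8-connectivity structuring element
_MOORE = np.ones((3, 3), dtype=bool)


@dataclass
class ClassifiedField:
    """Per-cell passability classes on the flow-field raster."""

    grid: GridSpec
    classes: np.ndarray
    threshold: float
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if arr.shape != self.grid.shape:
            raise ValueError("classes shape does not match grid")
        if not np.isin(arr, (PASSABLE, IMPASSABLE, BOUNDARY)).all():
            raise ValueError("classes must be 0 (passable), 1 (impassable) or 2 (boundary)")
        self.classes = arr.astype(np.int8)

    @property
    def passable(self) -> np.ndarray:
        return self.classes == PASSABLE

    @property
    def boundary(self) -> np.ndarray:
        return self.classes == BOUNDARY


def classify_field(field: VelocityField, threshold: float) -> ClassifiedField:
    """Classify every cell against a burst-speed threshold.

    passable  : speed <  threshold
    impassable: speed >= threshold  (an elver exactly at its burst speed
                makes no headway, so the tie goes to impassable)
    boundary  : nodata (no water)
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    classes = np.where(field.nodata, BOUNDARY,
                       np.where(field.speed < threshold, PASSABLE, IMPASSABLE))
    return ClassifiedField(grid=field.grid, classes=classes, threshold=threshold,
                           meta=dict(field.meta))


@dataclass(frozen=True)
class AreaFractions:
    """Class shares of a classified field; the first three sum to 1."""

    passable: float
    impassable: float
    boundary: float
    passable_wetted: float  # passable share of non-boundary (wetted) cells


def area_fractions(cf: ClassifiedField) -> AreaFractions:
    total = cf.classes.size
    if total == 0:
        raise ValueError("empty grid")
    n_pass = int(np.count_nonzero(cf.classes == PASSABLE))
    n_imp = int(np.count_nonzero(cf.classes == IMPASSABLE))
    n_bnd = int(np.count_nonzero(cf.classes == BOUNDARY))
    wetted = n_pass + n_imp
    return AreaFractions(
        passable=n_pass / total,
        impassable=n_imp / total,
        boundary=n_bnd / total,
        passable_wetted=n_pass / wetted if wetted else float("nan"),
    )


class PathResult(NamedTuple):
    connected: bool
    path: list[tuple[int, int]] | None  # downstream -> upstream witness


def _entry_sources(cf: ClassifiedField) -> np.ndarray:
    """Passable cells an entering agent can occupy after at most one move.

    Agents enter on any wetted (non-boundary) cell of the downstream edge row
    and may immediately step onto a passable Moore neighbour, so the search is
    seeded with passable downstream-edge cells *and* passable neighbours of
    wetted downstream-edge cells. This keeps "no path" exactly equivalent to
    "no automaton can ever ascend".
    """
    n, m = cf.grid.shape
    passable = cf.passable
    sources = np.zeros((n, m), dtype=bool)
    sources[n - 1] = passable[n - 1]
    entry = ~cf.boundary[n - 1]
    if entry.any():
        reach = np.zeros((n, m), dtype=bool)
        reach[n - 1] = entry
        reach = ndimage.binary_dilation(reach, structure=_MOORE)
        sources |= reach & passable
    return sources


def has_continuous_path(cf: ClassifiedField) -> PathResult:
    """Test for a Moore-connected passable route from entry to exit.

    Returns whether any chain of passable cells links the downstream edge
    (row n-1, as reachable by an entering agent) to the upstream edge
    (row 0), plus a breadth-first witness path when one exists.
    """
    n, m = cf.grid.shape
    passable = cf.passable
    sources = _entry_sources(cf)
    if not sources.any() or not passable[0].any():
        return PathResult(False, None)
    # fast boolean check: connected-component labels
    labels, _ = ndimage.label(passable, structure=_MOORE)
    if not np.intersect1d(labels[sources], labels[0][passable[0]]).size:
        return PathResult(False, None)
    # witness by BFS from the source set
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    queue: deque[tuple[int, int]] = deque()
    for i, j in zip(*np.nonzero(sources)):
        parent[(int(i), int(j))] = None
        queue.append((int(i), int(j)))
    goal = None
    while queue:
        i, j = queue.popleft()
        if i == 0:
            goal = (i, j)
            break
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < n and 0 <= nj < m and passable[ni, nj] \
                        and (ni, nj) not in parent:
                    parent[(ni, nj)] = (i, j)
                    queue.append((ni, nj))
    assert goal is not None  # label check guarantees reachability
    path = [goal]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()  # downstream source -> upstream goal
    return PathResult(True, path)


# ---------------------------------------------------------------------------
# I/O — classified grids reuse the delimited grid format with an integer body
# ---------------------------------------------------------------------------

def write_classified(cf: ClassifiedField, path) -> None:
    extra = {
        "classes": "passable:0,impassable:1,boundary:2",
        "threshold_ms": repr(float(cf.threshold)),
    }
    body = cf.classes.astype(float)
    _write_raster(path, "classified", cf.grid, body, extra, fmt="%d")


def read_classified(path) -> ClassifiedField:
    header, body = _read_raster(path)
    grid = GridSpec(int(header["n_streamwise"]), int(header["n_spanwise"]),
                    float(header["cell_size_m"]))
    return ClassifiedField(grid=grid, classes=body.astype(np.int8),
                           threshold=float(header.get("threshold_ms", "nan")))
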