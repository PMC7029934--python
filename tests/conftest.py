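"""Shared fixtures: small hand-built fields and classified grids."""

from __future__ import annotations

import numpy as np
import pytest

from eelpass.classify import BOUNDARY, IMPASSABLE, PASSABLE, ClassifiedField
from eelpass.flowfield import GridSpec, VelocityField


def uniform_field(speed: float, n: int = 20, m: int = 5,
                  cell: float = 5e-4) -> VelocityField:
    grid = GridSpec(n, m, cell)
    return VelocityField(grid=grid, speed=np.full(grid.shape, speed))


def corridor_field(speed: float, n_rows: int, cell: float = 5e-4) -> VelocityField:
    """Width-1 uniform corridor: the straight-ascent closed-form case."""
    grid = GridSpec(n_rows, 1, cell)
    return VelocityField(grid=grid, speed=np.full(grid.shape, speed))


def classified_from_array(classes, cell: float = 5e-4,
                          threshold: float = 0.3) -> ClassifiedField:
    arr = np.asarray(classes, dtype=np.int8)
    grid = GridSpec(arr.shape[0], arr.shape[1], cell)
    return ClassifiedField(grid=grid, classes=arr, threshold=threshold)


@pytest.fixture
def all_passable_10x6() -> ClassifiedField:
    return classified_from_array(np.zeros((10, 6), dtype=np.int8))


@pytest.fixture
def cul_de_sac_10x6() -> ClassifiedField:
    """Dead-end channel (column 1, blocked above row 4) plus a clear route
    (column 4). Fall-back is required to escape the dead end and re-route."""
    c = np.full((10, 6), IMPASSABLE, dtype=np.int8)
    c[9, :] = PASSABLE                  # spawn row fully open
    c[0, :] = PASSABLE                  # success line
    c[1:10, 4] = PASSABLE               # the through-route
    c[4:10, 1] = PASSABLE               # the cul-de-sac, dead-ends at row 4
    return classified_from_array(c)


@pytest.fixture
def blocked_10x6() -> ClassifiedField:
    """A fully impassable spanwise row separates entry from exit."""
    c = np.zeros((10, 6), dtype=np.int8)
    c[5, :] = IMPASSABLE
    return classified_from_array(c)
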