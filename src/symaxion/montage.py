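"""Electrode montage: the 9x9 scalp grid and its left-right symmetric pairs.

A 62-channel cap (10-20 extended system) is embedded into a 9x9 matrix that
preserves the anterior-posterior / left-right arrangement of the electrodes.
Midline ("z") electrodes occupy the central column (column 4); every lateral
electrode has a mirror partner in the opposite hemisphere (same row, columns
summing to 8), giving 27 symmetric pairs.  The pair numbering follows the
reading order of the left hemisphere: left electrodes are numbered 1..27
anterior to posterior, left to right, and each right-hemisphere partner is
numbered i+27.  All public indices in this module are 0-based; the 1-based
convention above is used only in documentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

GRID_SIZE = 9
MID_COL = 4
N_CHANNELS = 62
N_PAIRS = 27


class MontageError(ValueError):
    """Raised when an electrode layout violates the grid/symmetry contract."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Immutable description of an electrode cap embedded in a square grid.

    Parameters
    ----------
    names
        Channel labels, in the order signals are stored (reading order of the
        grid for the default cap).
    grid_cell
        Per-channel ``(row, col)`` cell, each cell occupied at most once.
    is_midline
        Per-channel flag; midline channels sit in the central column and are
        excluded from symmetric pairing.
    """

    names: tuple[str, ...]
    grid_cell: tuple[tuple[int, int], ...]
    is_midline: tuple[bool, ...]
    lateral_order: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.grid_cell) == len(self.is_midline) == n):
            raise MontageError("names, grid_cell and is_midline lengths differ")
        if len(set(self.names)) != n:
            raise MontageError("duplicate channel names")
        cells = set()
        for (r, c), mid in zip(self.grid_cell, self.is_midline):
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
                raise MontageError(f"cell ({r}, {c}) outside the {GRID_SIZE}x{GRID_SIZE} grid")
            if (r, c) in cells:
                raise MontageError(f"cell ({r}, {c}) occupied twice")
            cells.add((r, c))
            if mid != (c == MID_COL):
                raise MontageError(
                    f"midline flag of cell ({r}, {c}) inconsistent with column {MID_COL}"
                )
        object.__setattr__(self, "lateral_order", self._build_lateral_order())

    def _build_lateral_order(self) -> tuple[int, ...]:
        cell_to_idx = {cell: i for i, cell in enumerate(self.grid_cell)}
        left = [
            (r, c)
            for (r, c), mid in zip(self.grid_cell, self.is_midline)
            if not mid and c < MID_COL
        ]
        left.sort()  # reading order: anterior->posterior, left->right
        order: list[int] = []
        for r, c in left:
            mirror = (r, 2 * MID_COL - c)
            if mirror not in cell_to_idx:
                name = self.names[cell_to_idx[(r, c)]]
                raise MontageError(f"channel {name} at ({r}, {c}) has no mirror partner")
        n_right = sum(1 for (r, c), m in zip(self.grid_cell, self.is_midline) if not m and c > MID_COL)
        if n_right != len(left):
            raise MontageError("unequal numbers of left and right lateral channels")
        order = [cell_to_idx[cell] for cell in left]
        order += [cell_to_idx[(r, 2 * MID_COL - c)] for r, c in left]
        return tuple(order)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def n_pairs(self) -> int:
        return len(self.lateral_order) // 2

    @property
    def occupancy(self) -> np.ndarray:
        """Boolean 9x9 mask of occupied cells."""
        mask = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
        rows, cols = zip(*self.grid_cell)
        mask[list(rows), list(cols)] = True
        return mask

    @property
    def lateral_mask(self) -> np.ndarray:
        """Boolean 9x9 mask of occupied non-midline cells."""
        mask = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
        for (r, c), mid in zip(self.grid_cell, self.is_midline):
            if not mid:
                mask[r, c] = True
        return mask

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def _layout_from_rows(rows: list[tuple[str, int, int, bool]]) -> ElectrodeLayout:
    names, cells, mids = [], [], []
    for name, r, c, mid in rows:
        names.append(name)
        cells.append((int(r), int(c)))
        mids.append(bool(mid))
    return ElectrodeLayout(tuple(names), tuple(cells), tuple(mids))


def load_layout(path: str | Path) -> ElectrodeLayout:
    """Load a montage from a CSV table with columns name,row,col,midline."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = [
            (row["name"], int(row["row"]), int(row["col"]), bool(int(row["midline"])))
            for row in reader
        ]
    return _layout_from_rows(rows)


def build_default_layout() -> ElectrodeLayout:
    """The canonical 62-channel cap on the 9x9 grid.

    Frontal-pole and anterior-frontal rows are sparse (3 and 2 electrodes),
    the five central rows (F, FC, C, CP, P) span the full grid width, the
    parieto-occipital row holds 7 electrodes and the occipital row 5 (CB1/O1/
    OZ/O2/CB2).  This yields 62 occupied cells, 8 midline channels and 27
    symmetric pairs.
    """
    src = resources.files("symaxion.data").joinpath("montage62.csv")
    with resources.as_file(src) as path:
        layout = load_layout(path)
    if layout.n_channels != N_CHANNELS or layout.n_pairs != N_PAIRS:
        raise MontageError("bundled default montage is corrupt")
    return layout


def symmetric_pairs(layout: ElectrodeLayout) -> list[tuple[int, int]]:
    """Left/right mirror pairs as (left_index, right_index) channel indices.

    Ordered by the lateral numbering, i.e. pair ``i`` (0-based) corresponds to
    lateral positions ``i`` and ``i + n_pairs``.
    """
    k = layout.n_pairs
    return [(layout.lateral_order[i], layout.lateral_order[i + k]) for i in range(k)]


def vector_to_grid(values: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Scatter per-channel values onto the 9x9 grid; empty cells are 0.

    ``values`` may have arbitrary leading dimensions; the channel axis must be
    last.  The operation is invertible via :func:`grid_to_vector`.
    """
    values = np.asarray(values)
    if values.shape[-1] != layout.n_channels:
        raise ValueError(
            f"expected {layout.n_channels} channels on the last axis, got {values.shape[-1]}"
        )
    grid = np.zeros(values.shape[:-1] + (GRID_SIZE, GRID_SIZE), dtype=values.dtype)
    rows, cols = zip(*layout.grid_cell)
    grid[..., list(rows), list(cols)] = values
    return grid


def grid_to_vector(grid: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Gather channel values back out of a grid (inverse of vector_to_grid)."""
    grid = np.asarray(grid)
    if grid.shape[-2:] != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"expected trailing {GRID_SIZE}x{GRID_SIZE} axes, got {grid.shape[-2:]}")
    rows, cols = zip(*layout.grid_cell)
    return grid[..., list(rows), list(cols)]
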