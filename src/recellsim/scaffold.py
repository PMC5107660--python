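"""Decellularized-scaffold environment.

The scaffold is a cubic lattice of ``grid_size**3`` patches (default
``32**3 = 32,768``).  Integer patch coordinates run from ``-grid_size//2`` to
``grid_size//2 - 1`` per axis (``-16..15`` by default).  Each patch carries a
substrate concentration and can hold at most one cell.

The baseline substrate field is radial in each x-y plane,

    c(x, y, z) = scale * sqrt(x**2 + y**2) / divisor,

with ``scale = 20`` and ``divisor = 21.2`` by default, so the concentration is
lowest (0) on the central z-axis and highest at the in-plane corners.  The
field has no z-dependence: every horizontal slice sees the same gradient,
which gives motile cells a chemotactic impetus toward the scaffold border.
Engrafted cells locally raise the concentration of their patch by
``c_amount`` (default 1) and the increase is withdrawn when the cell dies.
Concentrations are clamped at 0 from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Patch",
    "ScaffoldState",
    "NEIGHBOR_OFFSETS",
]

# The 26 offsets at Chebyshev distance 1 (a 3x3x3 cube minus the center).
NEIGHBOR_OFFSETS: np.ndarray = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)

EMPTY = -1  # occupancy sentinel: no cell on the patch


@dataclass
class Patch:
    """A view onto one lattice patch of a :class:`ScaffoldState`."""

    state: "ScaffoldState"
    coords: tuple[int, int, int]

    @property
    def c_patch(self) -> float:
        return float(self.state.substrate[self.state._index(self.coords)])

    @property
    def occupied(self) -> int | None:
        """Index of the occupying cell, or ``None`` if the patch is empty."""
        cid = int(self.state.occupancy[self.state._index(self.coords)])
        return None if cid == EMPTY else cid


class ScaffoldState:
    """The lattice of patches: substrate field plus single-cell occupancy.

    Parameters
    ----------
    grid_size:
        Number of patches per axis.
    c_formula_scale, c_formula_divisor:
        Constants of the baseline radial substrate formula.
    c_amount:
        Default concentration deposited at engraftment / withdrawn at death.
    """

    def __init__(
        self,
        grid_size: int = 32,
        c_formula_scale: float = 20.0,
        c_formula_divisor: float = 21.2,
        c_amount: float = 1.0,
    ) -> None:
        if grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        self.grid_size = int(grid_size)
        self.c_formula_scale = float(c_formula_scale)
        self.c_formula_divisor = float(c_formula_divisor)
        self.c_amount = float(c_amount)
        self.lo = -(self.grid_size // 2)
        self.hi = self.lo + self.grid_size - 1  # inclusive upper bound

        coords = np.arange(self.lo, self.hi + 1)
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        base_plane = self.c_formula_scale * np.sqrt(xx**2 + yy**2) / self.c_formula_divisor
        # z-invariant field, broadcast along the third axis
        self.baseline = np.repeat(base_plane[:, :, None], self.grid_size, axis=2)
        self.substrate = self.baseline.copy()
        self.occupancy = np.full((self.grid_size,) * 3, EMPTY, dtype=np.int64)

    # -- coordinate helpers -------------------------------------------------

    def in_bounds(self, coords) -> bool:
        x, y, z = coords
        return all(self.lo <= v <= self.hi for v in (x, y, z))

    def _check(self, coords) -> None:
        if not self.in_bounds(coords):
            raise IndexError(
                f"coordinates {tuple(coords)} outside lattice extent "
                f"[{self.lo}, {self.hi}]"
            )

    def _index(self, coords) -> tuple[int, int, int]:
        x, y, z = coords
        return (int(x) - self.lo, int(y) - self.lo, int(z) - self.lo)

    def patch(self, coords) -> Patch:
        self._check(coords)
        return Patch(self, (int(coords[0]), int(coords[1]), int(coords[2])))

    @property
    def n_patches(self) -> int:
        return self.grid_size**3

    # -- substrate ----------------------------------------------------------

    def substrate_concentration(self, x: int, y: int, z: int) -> float:
        """Baseline substrate concentration of patch ``(x, y, z)``.

        Evaluates ``scale * sqrt(x**2 + y**2) / divisor``; independent of z.
        """
        self._check((x, y, z))
        return float(self.c_formula_scale * np.hypot(x, y) / self.c_formula_divisor)

    def concentration_at(self, coords) -> float:
        """Current (baseline + deposits) concentration at ``coords``."""
        self._check(coords)
        return float(self.substrate[self._index(coords)])

    def deposit_substrate(self, coords, c_amount: float | None = None) -> float:
        """Raise the patch concentration by ``c_amount`` (engraftment event)."""
        self._check(coords)
        amount = self.c_amount if c_amount is None else float(c_amount)
        idx = self._index(coords)
        self.substrate[idx] += amount
        return float(self.substrate[idx])

    def decay_substrate(self, coords, c_amount: float | None = None) -> float:
        """Lower the patch concentration by ``c_amount``, floored at 0 (death)."""
        self._check(coords)
        amount = self.c_amount if c_amount is None else float(c_amount)
        idx = self._index(coords)
        self.substrate[idx] = max(0.0, self.substrate[idx] - amount)
        return float(self.substrate[idx])

    # -- neighborhood -------------------------------------------------------

    def neighbors(self, coords) -> list[tuple[int, int, int]]:
        """In-bounds patches at Chebyshev distance 1 (up to 26), no wraparound."""
        self._check(coords)
        x, y, z = (int(v) for v in coords)
        out = []
        for dx, dy, dz in NEIGHBOR_OFFSETS:
            n = (x + dx, y + dy, z + dz)
            if self.in_bounds(n):
                out.append(n)
        return out

    def occupied_neighbor_count(self, coords) -> int:
        """Number of occupied patches among the (up to 26) neighbors."""
        return sum(
            1
            for n in self.neighbors(coords)
            if self.occupancy[self._index(n)] != EMPTY
        )

    # -- occupancy ----------------------------------------------------------

    def is_occupied(self, coords) -> bool:
        self._check(coords)
        return bool(self.occupancy[self._index(coords)] != EMPTY)

    def occupy(self, coords, cell_id: int) -> None:
        self._check(coords)
        idx = self._index(coords)
        if self.occupancy[idx] != EMPTY:
            raise ValueError(f"patch {tuple(coords)} already occupied")
        self.occupancy[idx] = cell_id

    def vacate(self, coords) -> None:
        self._check(coords)
        self.occupancy[self._index(coords)] = EMPTY

    def iter_coords(self) -> Iterator[tuple[int, int, int]]:
        rng = range(self.lo, self.hi + 1)
        for x in rng:
            for y in rng:
                for z in rng:
                    yield (x, y, z)
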