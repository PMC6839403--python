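"""Cell records and the struct-of-arrays container used by the simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class CellType(IntEnum):
    """The three cell types of the competition model.

    ``TARGET`` cells are susceptible, ``INHIBITOR`` cells carry the
    contact-dependent inhibition system, and ``INHIBITED_TARGET`` cells are
    targets whose growth rate has been reduced after intoxication.
    """

    TARGET = 0
    INHIBITOR = 1
    INHIBITED_TARGET = 2


#: Strain of each cell type: inhibited targets belong to the target strain.
STRAIN_OF = {
    CellType.TARGET: "target",
    CellType.INHIBITOR: "inhibitor",
    CellType.INHIBITED_TARGET: "target",
}


@dataclass
class Cell:
    """A single rigid-capsule cell.

    Lengths are cylinder lengths (pole-cap centers are ``length/2`` from the
    cell center along the axis); all distances in micrometers, angles in
    radians.
    """

    id: int
    parent_id: int
    center: np.ndarray
    angle: float
    length: float
    radius: float
    cell_type: CellType
    target_length: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (2,):
            raise ValueError("cell center must be a 2D point")


@dataclass
class CellCollection:
    """Columnar storage for a population of capsule cells.

    All arrays share the same length ``n``; row order is positional, while
    ``ids`` are persistent across timesteps and divisions.
    """

    ids: np.ndarray
    parent_ids: np.ndarray
    centers: np.ndarray  # (n, 2) um
    angles: np.ndarray  # rad
    lengths: np.ndarray  # cylinder length, um
    radii: np.ndarray  # um
    types: np.ndarray  # int8, CellType values
    target_lengths: np.ndarray  # um, pole-to-pole division thresholds
    growth_rates: np.ndarray = field(default=None)  # realized, h^-1

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.growth_rates is None:
            self.growth_rates = np.zeros(n)
        for name in ("parent_ids", "angles", "lengths", "radii", "types",
                     "target_lengths", "growth_rates"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} length mismatch")
        if self.centers.shape != (n, 2):
            raise ValueError("centers must have shape (n, 2)")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls) -> "CellCollection":
        return cls(
            ids=np.empty(0, dtype=np.int64),
            parent_ids=np.empty(0, dtype=np.int64),
            centers=np.empty((0, 2)),
            angles=np.empty(0),
            lengths=np.empty(0),
            radii=np.empty(0),
            types=np.empty(0, dtype=np.int8),
            target_lengths=np.empty(0),
        )

    @classmethod
    def from_cells(cls, cells: list[Cell]) -> "CellCollection":
        if not cells:
            return cls.empty()
        return cls(
            ids=np.array([c.id for c in cells], dtype=np.int64),
            parent_ids=np.array([c.parent_id for c in cells], dtype=np.int64),
            centers=np.array([c.center for c in cells], dtype=float),
            angles=np.array([c.angle for c in cells], dtype=float),
            lengths=np.array([c.length for c in cells], dtype=float),
            radii=np.array([c.radius for c in cells], dtype=float),
            types=np.array([int(c.cell_type) for c in cells], dtype=np.int8),
            target_lengths=np.array([c.target_length for c in cells], dtype=float),
        )

    def cell(self, pos: int) -> Cell:
        """Materialize the cell at positional index ``pos``."""
        return Cell(
            id=int(self.ids[pos]),
            parent_id=int(self.parent_ids[pos]),
            center=self.centers[pos].copy(),
            angle=float(self.angles[pos]),
            length=float(self.lengths[pos]),
            radius=float(self.radii[pos]),
            cell_type=CellType(int(self.types[pos])),
            target_length=float(self.target_lengths[pos]),
        )

    def to_cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n)]

    def copy(self) -> "CellCollection":
        return CellCollection(
            ids=self.ids.copy(),
            parent_ids=self.parent_ids.copy(),
            centers=self.centers.copy(),
            angles=self.angles.copy(),
            lengths=self.lengths.copy(),
            radii=self.radii.copy(),
            types=self.types.copy(),
            target_lengths=self.target_lengths.copy(),
            growth_rates=self.growth_rates.copy(),
        )

    def axes(self) -> np.ndarray:
        """Unit axis vectors, shape (n, 2)."""
        return np.stack([np.cos(self.angles), np.sin(self.angles)], axis=1)

    def id_to_pos(self) -> dict[int, int]:
        return {int(cid): i for i, cid in enumerate(self.ids)}
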