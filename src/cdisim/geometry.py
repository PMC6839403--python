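"""Capsule (spherocylinder) primitives in the plane and contact detection.

Cells are rigid 2D capsules: a core segment of some length plus a circular
cap of fixed radius swept along it. Contact queries use a uniform grid hash
whose bin width is at least the largest capsule extent, making a 3x3
neighborhood search exhaustive; results are identical to the brute-force
all-pairs computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cdisim import _kernels
from cdisim.cells import CellCollection

#: Default surface-separation tolerance below which two cells are "in contact".
DEFAULT_CONTACT_TOL = 0.05  # um


class InvalidGeometryError(ValueError):
    """Raised for non-finite or otherwise invalid geometric inputs."""


@dataclass(frozen=True)
class Capsule:
    """A 2D capsule: segment of ``length`` centered at ``center`` along
    ``axis``, swept by a disc of ``radius``.

    Parameters
    ----------
    center : (2,) array-like
        Midpoint of the core segment, um.
    axis : (2,) array-like
        Unit direction of the core segment.
    length : float
        Core segment length (cylinder length, pole-cap center to pole-cap
        center), um. May be zero (a disc).
    radius : float
        Cap radius, um. Strictly positive.
    """

    center: tuple[float, float]
    axis: tuple[float, float]
    length: float
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        if c.shape != (2,) or a.shape != (2,):
            raise InvalidGeometryError("center and axis must be 2D")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(a))
                and np.isfinite(self.length) and np.isfinite(self.radius)):
            raise InvalidGeometryError("non-finite capsule parameters")
        if self.length < 0:
            raise InvalidGeometryError("capsule length must be >= 0")
        if self.radius <= 0:
            raise InvalidGeometryError("capsule radius must be > 0")
        if abs(np.hypot(a[0], a[1]) - 1.0) > 1e-9:
            raise InvalidGeometryError("capsule axis must be a unit vector")
        object.__setattr__(self, "center", (float(c[0]), float(c[1])))
        object.__setattr__(self, "axis", (float(a[0]), float(a[1])))

    @classmethod
    def from_angle(cls, center, angle: float, length: float, radius: float) -> "Capsule":
        return cls(tuple(center), (float(np.cos(angle)), float(np.sin(angle))),
                   float(length), float(radius))

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.axis[1], self.axis[0]))

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Pole-cap centers (ends of the core segment)."""
        c = np.asarray(self.center)
        u = np.asarray(self.axis)
        h = 0.5 * self.length
        return c - h * u, c + h * u

    @property
    def extent(self) -> float:
        """Pole-to-pole size: length + 2*radius."""
        return self.length + 2.0 * self.radius


def capsule_distance(a: Capsule, b: Capsule) -> float:
    """Surface separation between two capsules, um.

    Minimum distance between the two core segments minus the sum of radii.
    Negative when the capsules overlap; symmetric in its arguments.
    """
    pa, _ = a.endpoints
    pb, _ = b.endpoints
    ua = np.asarray(a.axis)
    ub = np.asarray(b.axis)
    _, _, d = _kernels.seg_seg_closest(
        pa[0], pa[1], a.length * ua[0], a.length * ua[1],
        pb[0], pb[1], b.length * ub[0], b.length * ub[1])
    return float(d) - (a.radius + b.radius)


class ContactGraph:
    """The set of touching cell pairs for one snapshot of the population.

    Pairs are stored as positional indices ``(i, j)`` with ``i < j`` together
    with their signed surface separation (``<= tol``; negative separation is
    an overlap). The graph is symmetric by construction and contains no
    self-pairs.
    """

    def __init__(self, i: np.ndarray, j: np.ndarray, sep: np.ndarray,
                 n_cells: int, tol: float):
        self.i = np.asarray(i, dtype=np.int64)
        self.j = np.asarray(j, dtype=np.int64)
        self.sep = np.asarray(sep, dtype=float)
        self.n_cells = int(n_cells)
        self.tol = float(tol)

    def __len__(self) -> int:
        return len(self.i)

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    @property
    def overlaps(self) -> np.ndarray:
        """Overlap depth per pair (um, >= 0; 0 when merely within tolerance)."""
        return np.maximum(0.0, -self.sep)

    def pair_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in zip(self.i, self.j)}

    def degrees(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Number of contacts per cell; with ``mask``, count only contacts
        with cells for which ``mask`` is True."""
        out = np.zeros(self.n_cells, dtype=np.int64)
        if mask is None:
            np.add.at(out, self.i, 1)
            np.add.at(out, self.j, 1)
        else:
            mask = np.asarray(mask, dtype=bool)
            np.add.at(out, self.i, mask[self.j].astype(np.int64))
            np.add.at(out, self.j, mask[self.i].astype(np.int64))
        return out

    def restrict(self, tol: float) -> "ContactGraph":
        """Sub-graph of pairs with separation <= tol (tol <= self.tol)."""
        if tol > self.tol:
            raise ValueError("cannot restrict to a larger tolerance")
        keep = self.sep <= tol
        return ContactGraph(self.i[keep], self.j[keep], self.sep[keep],
                           self.n_cells, tol)


def _as_arrays(cells) -> tuple[np.ndarray, ...]:
    if isinstance(cells, CellCollection):
        return (cells.centers[:, 0], cells.centers[:, 1], cells.angles,
                cells.lengths, cells.radii)
    caps = list(cells)
    cx = np.array([c.center[0] for c in caps])
    cy = np.array([c.center[1] for c in caps])
    ang = np.array([c.angle for c in caps])
    lg = np.array([c.length for c in caps])
    rad = np.array([c.radius for c in caps])
    return cx, cy, ang, lg, rad


def build_contacts(cells, tol: float = DEFAULT_CONTACT_TOL) -> ContactGraph:
    """Find all cell pairs whose surface separation is at most ``tol``.

    Parameters
    ----------
    cells : CellCollection or sequence of Capsule
        The population; pair indices refer to positional order.
    tol : float
        Contact tolerance (um), >= 0 for physical contact queries (negative
        values select only overlapping pairs and are allowed).

    Returns
    -------
    ContactGraph
        Identical to the all-pairs O(n^2) result, computed via a grid hash.
    """
    cx, cy, ang, lg, rad = _as_arrays(cells)
    n = len(cx)
    if n < 2:
        return ContactGraph(np.empty(0, np.int64), np.empty(0, np.int64),
                            np.empty(0), n, tol)
    if not (np.all(np.isfinite(cx)) and np.all(np.isfinite(cy))
            and np.all(np.isfinite(ang))):
        raise InvalidGeometryError("non-finite cell coordinates")
    cell_size = float(np.max(lg + 2.0 * rad)) + max(tol, 0.0) + 1e-9
    pi, pj, sep = _kernels.contact_pairs(
        np.ascontiguousarray(cx, dtype=float),
        np.ascontiguousarray(cy, dtype=float),
        np.ascontiguousarray(ang, dtype=float),
        np.ascontiguousarray(lg, dtype=float) * 0.5,
        np.ascontiguousarray(rad, dtype=float),
        float(tol), cell_size)
    return ContactGraph(pi, pj, sep, n, tol)
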