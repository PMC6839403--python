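"""Cell growth, division and viscous overlap relaxation.

Growth is exponential elongation, ``dL = rate * L * dt``, attenuated by local
overlap pressure so that jammed cells in the colony interior elongate little
while cells at the free edge realize their full unconstrained elongation.
Overlaps created by growth are resolved by damped pairwise pushout sweeps
(a sequential projection scheme), which is what transports cells radially
outward as the colony expands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cdisim import _kernels
from cdisim.cells import Cell, CellCollection, CellType
from cdisim.geometry import ContactGraph, InvalidGeometryError

logger = logging.getLogger(__name__)

#: Residual overlap below which a pair counts as resolved (um).
DEFAULT_RESIDUAL_TOL = 0.01
DEFAULT_MAX_RELAX_ITER = 50
DEFAULT_DRAG_DAMPING = 0.7
DEFAULT_TORQUE_GAIN = 0.5
#: Growth attenuation per um of summed overlap depth on a cell.
DEFAULT_PRESSURE_SENSITIVITY = 5.0


class StateError(ValueError):
    """Raised for invalid cell-type or growth-state inputs."""


@dataclass
class GrowthState:
    """Growth bookkeeping for a single cell."""

    base_rate: float  # alpha, h^-1
    target_length: float  # division threshold, um
    realized_elongation: float = 0.0  # um, last step

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise StateError("growth rate must be >= 0")
        if self.target_length <= 0:
            raise StateError("target length must be > 0")


def effective_growth_rate(cell_type: CellType, alpha: float,
                          delta: float, beta: float) -> float:
    """Type-dependent growth rate: targets grow at ``alpha``, inhibitors pay
    the cost ``beta`` (rate ``alpha*(1-beta)``), inhibited targets suffer the
    toxicity ``delta`` (rate ``alpha*(1-delta)``)."""
    if not 0.0 <= delta <= 1.0:
        raise StateError("toxicity delta must be in [0, 1]")
    if not 0.0 <= beta < 1.0:
        raise StateError("cost beta must be in [0, 1)")
    if cell_type == CellType.TARGET:
        return alpha
    if cell_type == CellType.INHIBITOR:
        return alpha * (1.0 - beta)
    if cell_type == CellType.INHIBITED_TARGET:
        return alpha * (1.0 - delta)
    raise StateError(f"unknown cell type: {cell_type!r}")


def growth_rates(types: np.ndarray, alpha: float, delta: float,
                 beta: float) -> np.ndarray:
    """Vectorized :func:`effective_growth_rate` over a type array."""
    if not 0.0 <= delta <= 1.0:
        raise StateError("toxicity delta must be in [0, 1]")
    if not 0.0 <= beta < 1.0:
        raise StateError("cost beta must be in [0, 1)")
    lut = np.array([alpha, alpha * (1.0 - beta), alpha * (1.0 - delta)])
    t = np.asarray(types, dtype=np.int64)
    if t.size and (t.min() < 0 or t.max() > 2):
        raise StateError("unknown cell type code in array")
    return lut[t]


def unconstrained_elongation(length, rate, dt):
    """Unconstrained per-step elongation ``dL = rate * L * dt`` (um)."""
    if np.any(np.asarray(length) <= 0):
        raise StateError("cell length must be > 0")
    if dt <= 0:
        raise StateError("timestep must be > 0")
    return rate * np.asarray(length) * dt


@dataclass
class RelaxReport:
    """Outcome of one growth-and-relaxation step."""

    realized_elongation: np.ndarray  # um per cell
    iterations: int
    max_residual_overlap: float  # um
    jammed: bool  # residual above tolerance after the iteration budget


def relax_and_grow(cells: CellCollection, contacts: ContactGraph, dt: float,
                   rates: np.ndarray | float, *,
                   drag: float = DEFAULT_DRAG_DAMPING,
                   pressure_sensitivity: float = DEFAULT_PRESSURE_SENSITIVITY,
                   residual_tol: float = DEFAULT_RESIDUAL_TOL,
                   max_iter: int = DEFAULT_MAX_RELAX_ITER,
                   torque_gain: float = DEFAULT_TORQUE_GAIN,
                   freeze_depth: float | None = None) -> RelaxReport:
    """Advance poses and lengths by one timestep, in place.

    Order of operations: (1) each cell's overlap pressure (sum of overlap
    depths with its contacts) attenuates its unconstrained elongation by the
    factor ``max(0, 1 - pressure_sensitivity * pressure)``; (2) lengths are
    extended symmetrically about the cell center; (3) overlapping pairs are
    relaxed by damped Gauss-Seidel pushout until the maximum overlap falls
    below ``residual_tol`` or ``max_iter`` sweeps have run.

    ``contacts`` must have been built for the entry poses, with a skin wide
    enough to contain any pair that can come into contact during the step.
    Isolated cells do not move and realize their full elongation. The update
    is deterministic given its inputs.

    With ``freeze_depth`` set, jammed cells (growth factor < 0.3) deeper than
    that distance below the colony's outer radius are treated as static:
    pairs between two such cells are skipped during relaxation. Deep in a
    jammed colony these cells cannot move anyway, and skipping them makes the
    per-step cost scale with the expanding rim rather than the colony bulk.
    Colonies smaller than ``freeze_depth`` are unaffected.
    """
    n = cells.n
    if n == 0:
        return RelaxReport(np.empty(0), 0, 0.0, False)
    if dt <= 0:
        raise StateError("timestep must be > 0")
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n,))

    cx = cells.centers[:, 0]
    cy = cells.centers[:, 1]
    hl = 0.5 * cells.lengths

    sep = _kernels.pair_separations(cx, cy, cells.angles, hl, cells.radii,
                                    contacts.i, contacts.j)
    pressure = _kernels.overlap_pressure(sep, contacts.i, contacts.j, n,
                                         residual_tol)
    factor = np.maximum(0.0, 1.0 - pressure_sensitivity * pressure)

    # exponential elongation of the pole-to-pole extent: the extent is what
    # division conserves, so an unconstrained lineage's biomass compounds at
    # exactly `rate` per hour regardless of dt
    extent = cells.lengths + 2.0 * cells.radii
    d_unconstrained = extent * np.expm1(rates * dt)
    realized = factor * d_unconstrained
    cells.lengths += realized
    cells.growth_rates = realized / (extent * dt)

    pair_i, pair_j = contacts.i, contacts.j
    if freeze_depth is not None and n > 2:
        centroid = cells.centers.mean(axis=0)
        dist = np.hypot(cells.centers[:, 0] - centroid[0],
                        cells.centers[:, 1] - centroid[1])
        frozen = (dist < dist.max() - freeze_depth) & (factor < 0.3)
        if frozen.any():
            keep = ~(frozen[pair_i] & frozen[pair_j])
            pair_i = pair_i[keep]
            pair_j = pair_j[keep]

    iters, max_res = _kernels.relax_overlaps(
        cx, cy, cells.angles, 0.5 * cells.lengths, cells.radii,
        pair_i, pair_j, residual_tol, max_iter, drag, torque_gain)
    jammed = bool(max_res > residual_tol)
    if jammed:
        logger.debug("relaxation left residual overlap %.4f um after %d sweeps",
                     max_res, iters)
    return RelaxReport(realized, int(iters), float(max_res), jammed)


def draw_target_length(rng: np.random.Generator, mean: float, sd: float,
                       min_length: float) -> float:
    """Division target length ~ Normal(mean, sd), truncated below at
    ``min_length`` (resampling)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > min_length:
            return float(v)
    raise StateError("target-length distribution mass almost entirely below "
                     "the minimum length")


def maybe_divide(cell: Cell, rng: np.random.Generator, *,
                 target_mean: float = 3.5, target_sd: float = 0.35,
                 angle_jitter: float = 0.1) -> list[Cell]:
    """Divide a cell in half once it has reached its target length.

    ``target_length`` is a pole-to-pole extent (what microscopy measures);
    the cell divides when ``length + 2*radius >= target_length``. Returns
    ``[cell]`` unchanged below the threshold. Otherwise returns two daughters
    whose pole-to-pole extents exactly tile the parent's: each daughter has
    cylinder length ``(L - 2r)/2`` (extent exactly half the parent's) and
    center at ``+-(L + 2r)/4`` along the parent axis. Daughter axes are the
    parent axis rotated by independent Uniform(-angle_jitter, +angle_jitter)
    draws; daughter target lengths are fresh draws from the division-length
    distribution; cell type (including inhibited state) is inherited.

    Daughter ids are set to -1 (the engine assigns persistent ids);
    ``parent_id`` is the parent's id.
    """
    if cell.length + 2.0 * cell.radius < cell.target_length:
        return [cell]
    L, r = cell.length, cell.radius
    if L < 2.0 * r:
        raise InvalidGeometryError(
            f"cannot split a cell of length {L} with radius {r}: "
            "daughter length would be negative")
    u = np.array([np.cos(cell.angle), np.sin(cell.angle)])
    child_len = 0.5 * (L - 2.0 * r)
    offset = 0.25 * (L + 2.0 * r)
    daughters = []
    for sign in (-1.0, 1.0):
        ang = cell.angle + rng.uniform(-angle_jitter, angle_jitter)
        tgt = draw_target_length(rng, target_mean, target_sd, 2.0 * r)
        daughters.append(Cell(
            id=-1,
            parent_id=cell.id,
            center=cell.center + sign * offset * u,
            angle=float(ang),
            length=child_len,
            radius=r,
            cell_type=cell.cell_type,
            target_length=tgt,
        ))
    return daughters
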