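"""Simulation configuration, inoculation, the main loop, and snapshot I/O.

A run starts from a randomly inoculated central disc of target and inhibitor
cells and advances in fixed timesteps. Each step: rebuild contacts, reconcile
the stochastic reaction queue, fire due inhibition/recovery events, grow and
relax the cells mechanically, then divide cells that reached their target
length. Given identical parameters and seed the run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import time as _time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cdisim.cells import CellCollection, CellType
from cdisim.geometry import build_contacts
from cdisim.kinetics import (CdiParams, ReactionKind, ReactionQueue, fire,
                             sync_reactions)
from cdisim.mechanics import growth_rates, maybe_divide, relax_and_grow

logger = logging.getLogger(__name__)

SNAPSHOT_COLUMNS = ["id", "parent_id", "t_h", "x_um", "y_um", "angle_rad",
                    "length_um", "radius_um", "cell_type", "inhibited",
                    "growth_rate_h"]

class ConfigError(ValueError):
    """Raised for invalid simulation parameters; names the offending key."""


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one simulation run.

    Times in hours, distances in micrometers; ``inoculum_density`` is in
    cells per 1000 um^2 as in the source experiments.
    """

    alpha: float = float(np.log(2) / 0.5)  # growth rate, h^-1 (30-min doubling)
    eta: float = 0.0  # inhibition rate, h^-1 per contacting inhibitor
    delta: float = 0.0  # toxicity (fraction of growth rate removed)
    mu: float = 0.01  # recovery rate, h^-1
    beta: float = 0.0  # inhibitor cost (fraction)
    dt: float = 0.05  # h
    n_steps: int = 700
    inoculum_radius: float = 200.0  # um
    inoculum_density: float = 160.0  # cells per 1000 um^2
    inhibitor_fraction: float = 0.5
    cell_radius: float = 0.4  # um
    target_length_mean: float = 3.5  # um, pole-to-pole division length
    target_length_sd: float = 0.35  # um
    division_angle_jitter: float = 0.1  # rad
    contact_tol: float = 0.05  # um
    candidate_skin: float = 0.4  # um, pair-list margin for one step's motion
    residual_tol: float = 0.01  # um
    max_relax_iter: int = 50
    drag: float = 0.7  # pushout damping (viscous drag analogue)
    torque_gain: float = 0.5
    pressure_sensitivity: float = 10.0  # growth attenuation per um overlap
    freeze_depth: float = 0.0  # um below colony rim; > 0 makes the jammed core static
    seed: int = 0
    snapshot_interval: int = 100  # steps; 0 = final snapshot only

    def __post_init__(self) -> None:
        checks = [
            ("alpha", self.alpha >= 0),
            ("eta", self.eta >= 0),
            ("delta", 0.0 <= self.delta <= 1.0),
            ("mu", self.mu >= 0),
            ("beta", 0.0 <= self.beta < 1.0),
            ("dt", self.dt > 0),
            ("n_steps", self.n_steps >= 0),
            ("inoculum_radius", self.inoculum_radius > 0),
            ("inoculum_density", self.inoculum_density >= 0),
            ("inhibitor_fraction", 0.0 <= self.inhibitor_fraction <= 1.0),
            ("cell_radius", self.cell_radius > 0),
            ("target_length_mean", self.target_length_mean > 2 * self.cell_radius),
            ("target_length_sd", self.target_length_sd >= 0),
            ("contact_tol", self.contact_tol >= 0),
            ("snapshot_interval", self.snapshot_interval >= 0),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for parameter {key!r}: "
                                  f"{getattr(self, key)!r}")

    @property
    def cdi(self) -> CdiParams:
        return CdiParams(eta=self.eta, delta=self.delta, mu=self.mu,
                         beta=self.beta)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)

    def params_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def desk_profile(**overrides) -> SimulationParams:
    """Reduced-scale profile (inoculum radius 50 um, 350 steps) for quick
    desk runs; same physics as the full-scale default profile."""
    base = dict(inoculum_radius=50.0, n_steps=350, snapshot_interval=0)
    base.update(overrides)
    return SimulationParams(**base)


def full_profile(**overrides) -> SimulationParams:
    """Full-scale default profile: 200 um inoculum, 700 steps of 0.05 h."""
    return SimulationParams(**overrides)


def load_config(path: str | Path) -> SimulationParams:
    """Read a flat TOML config; every key optional, defaults apply."""
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    return SimulationParams.from_dict(data)


@dataclass
class Snapshot:
    """Time-stamped table of all cell records plus run metadata."""

    time: float
    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def inhibitor_proportion(self) -> float:
        """Inhibitors / all cells (inhibited targets count as targets)."""
        if len(self.frame) == 0:
            return float("nan")
        return float((self.frame["cell_type"] == "inhibitor").mean())


@dataclass
class Colony:
    """Mutable simulation state."""

    cells: CellCollection
    params: SimulationParams
    rng: np.random.Generator
    queue: ReactionQueue = field(default_factory=ReactionQueue)
    time: float = 0.0
    step_index: int = 0
    next_id: int = 0
    n_jammed_steps: int = 0
    n_inhibition_events: int = 0
    n_recovery_events: int = 0

    def counts_by_type(self) -> dict[str, int]:
        t = self.cells.types
        return {
            "target": int(np.sum(t == CellType.TARGET)),
            "inhibitor": int(np.sum(t == CellType.INHIBITOR)),
            "inhibited_target": int(np.sum(t == CellType.INHIBITED_TARGET)),
        }

    def radius(self) -> float:
        """Colony radius: max cell-center distance from the centroid."""
        if self.cells.n == 0:
            return 0.0
        c = self.cells.centers.mean(axis=0)
        return float(np.max(np.hypot(*(self.cells.centers - c).T)))


def _draw_target_lengths(rng: np.random.Generator, n: int, mean: float,
                         sd: float, lo: float) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out <= lo
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= lo
    return out


def inoculum_size(density: float, radius: float) -> int:
    """Founding cell count: ``round(density * pi * radius^2 / 1000)`` for a
    density in cells per 1000 um^2 and a radius in um."""
    return int(round(density * np.pi * radius * radius / 1000.0))


def inoculate(params: SimulationParams,
              rng: np.random.Generator | None = None) -> Colony:
    """Place the founding population uniformly at random in the central disc.

    ``N = round(density * pi * r^2 / 1000)`` cells get uniform positions and
    axis angles; ``round(N * inhibitor_fraction)`` of them are assigned the
    inhibitor type by a draw without replacement; initial cylinder lengths
    are uniform between birth length and the cell's division target length.
    Overlaps from random placement are relaxed away before t = 0.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    r = params.inoculum_radius
    n = inoculum_size(params.inoculum_density, r)
    if n == 0:
        colony = Colony(cells=CellCollection.empty(), params=params, rng=rng)
        return colony

    mean_area = (params.target_length_mean * 0.75 * 2 * params.cell_radius
                 + np.pi * params.cell_radius ** 2)
    packing = n * mean_area / (np.pi * r * r)
    if packing > 0.85:
        raise ConfigError(
            f"inoculum density {params.inoculum_density} cells/1000 um^2 "
            f"implies packing fraction {packing:.2f} > 0.85; cells cannot be "
            "placed without persistent overlap. Reduce inoculum_density or "
            "increase inoculum_radius.")

    rad = r * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    centers = np.stack([rad * np.cos(theta), rad * np.sin(theta)], axis=1)
    angles = rng.uniform(0.0, 2.0 * np.pi, n)
    # target lengths are pole-to-pole extents; newborns have extent
    # target/2, so initial extents are uniform between the two
    targets = _draw_target_lengths(rng, n, params.target_length_mean,
                                   params.target_length_sd,
                                   2.0 * params.cell_radius)
    extents = rng.uniform(0.5 * targets, targets)
    lengths = np.maximum(extents - 2.0 * params.cell_radius, 0.01)
    types = np.full(n, CellType.TARGET, dtype=np.int8)
    n_inhib = int(round(n * params.inhibitor_fraction))
    inhib_idx = rng.choice(n, size=n_inhib, replace=False)
    types[inhib_idx] = CellType.INHIBITOR

    cells = CellCollection(
        ids=np.arange(n, dtype=np.int64),
        parent_ids=np.full(n, -1, dtype=np.int64),
        centers=centers,
        angles=angles,
        lengths=lengths,
        radii=np.full(n, params.cell_radius, dtype=float),
        types=types,
        target_lengths=targets,
    )
    _relax_inoculum(cells, params)
    return Colony(cells=cells, params=params, rng=rng, next_id=n)


def _relax_inoculum(cells: CellCollection, params: SimulationParams,
                    rounds: int = 40) -> None:
    from cdisim import _kernels

    max_res = 0.0
    for _ in range(rounds):
        cand = build_contacts(cells, tol=params.candidate_skin)
        if len(cand) == 0:
            return
        # convergence is judged on a freshly built graph: large pushes can
        # create overlaps with pairs outside the current candidate list
        max_res = float(cand.overlaps.max())
        if max_res <= params.residual_tol:
            return
        _kernels.relax_overlaps(
            cells.centers[:, 0], cells.centers[:, 1], cells.angles,
            0.5 * cells.lengths, cells.radii, cand.i, cand.j,
            params.residual_tol, 20, params.drag, params.torque_gain)
    logger.warning("inoculum relaxation left residual overlap %.3f um", max_res)


def step(colony: Colony) -> Colony:
    """Advance one timestep of length ``dt``, in place.

    Order: rebuild contacts; reconcile the reaction queue; fire reactions due
    within the step window in putative-time order; grow and relax with
    type-dependent rates; divide cells that reached their target length.
    """
    p = colony.params
    cells = colony.cells
    t_end = colony.time + p.dt
    if cells.n > 0:
        candidates = build_contacts(cells, tol=p.candidate_skin)
        contacts = candidates.restrict(p.contact_tol)

        sync_reactions(contacts, cells.ids, cells.types, colony.queue,
                       p.cdi, colony.time, colony.rng)
        id2pos = cells.id_to_pos()
        while len(colony.queue) and colony.queue.peek().tau <= t_end:
            reaction = colony.queue.pop()
            pos = fire(reaction, id2pos, cells.types)
            if pos is not None:
                if reaction.kind == ReactionKind.INHIBITION:
                    colony.n_inhibition_events += 1
                else:
                    colony.n_recovery_events += 1

        rates = growth_rates(cells.types, p.alpha, p.delta, p.beta)
        report = relax_and_grow(
            cells, candidates, p.dt, rates,
            drag=p.drag, pressure_sensitivity=p.pressure_sensitivity,
            residual_tol=p.residual_tol, max_iter=p.max_relax_iter,
            torque_gain=p.torque_gain,
            freeze_depth=p.freeze_depth if p.freeze_depth > 0 else None)
        if report.jammed:
            colony.n_jammed_steps += 1

        _divide_cells(colony)

        if logger.isEnabledFor(logging.DEBUG):
            counts = colony.counts_by_type()
            logger.debug(
                "step %d t=%.2f h: %d cells (%d T / %d I / %d iT), "
                "queue=%d, max overlap=%.3f um",
                colony.step_index + 1, t_end, colony.cells.n,
                counts["target"], counts["inhibitor"],
                counts["inhibited_target"], len(colony.queue),
                report.max_residual_overlap)

    colony.time = t_end
    colony.step_index += 1
    return colony


def _divide_cells(colony: Colony) -> None:
    cells = colony.cells
    extents = cells.lengths + 2.0 * cells.radii
    div_pos = np.nonzero((extents >= cells.target_lengths)
                         & (cells.lengths >= 2.0 * cells.radii))[0]
    if len(div_pos) == 0:
        return
    p = colony.params
    keep = np.ones(cells.n, dtype=bool)
    keep[div_pos] = False
    daughters = []
    d_rates = []
    for pos in div_pos:
        parent = cells.cell(pos)
        kids = maybe_divide(parent, colony.rng,
                            target_mean=p.target_length_mean,
                            target_sd=p.target_length_sd,
                            angle_jitter=p.division_angle_jitter)
        for kid in kids:
            kid.id = colony.next_id
            colony.next_id += 1
            daughters.append(kid)
            d_rates.append(cells.growth_rates[pos])

    extra = CellCollection.from_cells(daughters)
    colony.cells = CellCollection(
        ids=np.concatenate([cells.ids[keep], extra.ids]),
        parent_ids=np.concatenate([cells.parent_ids[keep], extra.parent_ids]),
        centers=np.concatenate([cells.centers[keep], extra.centers]),
        angles=np.concatenate([cells.angles[keep], extra.angles]),
        lengths=np.concatenate([cells.lengths[keep], extra.lengths]),
        radii=np.concatenate([cells.radii[keep], extra.radii]),
        types=np.concatenate([cells.types[keep], extra.types]),
        target_lengths=np.concatenate([cells.target_lengths[keep],
                                       extra.target_lengths]),
        growth_rates=np.concatenate([cells.growth_rates[keep],
                                     np.asarray(d_rates, dtype=float)]),
    )


def take_snapshot(colony: Colony) -> Snapshot:
    """Tabulate the current population into the snapshot schema."""
    cells = colony.cells
    type_names = np.where(cells.types == CellType.INHIBITOR,
                          "inhibitor", "target")
    frame = pd.DataFrame({
        "id": cells.ids,
        "parent_id": cells.parent_ids,
        "t_h": np.full(cells.n, colony.time),
        "x_um": cells.centers[:, 0],
        "y_um": cells.centers[:, 1],
        "angle_rad": cells.angles,
        "length_um": cells.lengths,
        "radius_um": cells.radii,
        "cell_type": type_names,
        "inhibited": (cells.types == CellType.INHIBITED_TARGET).astype(int),
        "growth_rate_h": cells.growth_rates,
    }, columns=SNAPSHOT_COLUMNS)
    meta = {
        "params_hash": colony.params.params_hash(),
        "seed": colony.params.seed,
        "time_h": colony.time,
        "step": colony.step_index,
        "n_cells": cells.n,
    }
    return Snapshot(time=colony.time, frame=frame, meta=meta)


def run(params: SimulationParams, *, keep_colony: bool = False,
        progress: bool = False):
    """Run a full simulation and return its snapshots.

    Snapshots are taken at t = 0, every ``snapshot_interval`` steps (when the
    interval is positive) and at the final step. With ``keep_colony`` the
    final :class:`Colony` is returned as a second value.
    """
    t0 = _time.perf_counter()
    colony = inoculate(params)
    snapshots = [take_snapshot(colony)]
    iterator = range(1, params.n_steps + 1)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="cdisim", unit="step")
        except ImportError:
            pass
    for k in iterator:
        step(colony)
        if params.snapshot_interval and k % params.snapshot_interval == 0 \
                and k != params.n_steps:
            snapshots.append(take_snapshot(colony))
    if params.n_steps > 0:
        final = take_snapshot(colony)
        final.meta["wall_clock_s"] = round(_time.perf_counter() - t0, 3)
        final.meta["n_jammed_steps"] = colony.n_jammed_steps
        snapshots.append(final)
    if keep_colony:
        return snapshots, colony
    return snapshots


def write_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    """Write a snapshot as a TSV table with a '#'-prefixed header block."""
    path = Path(path)
    buf = io.StringIO()
    for key, value in snapshot.meta.items():
        buf.write(f"# {key}={value}\n")
    snapshot.frame.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_snapshot(path: str | Path) -> Snapshot:
    """Read a snapshot TSV written by :func:`write_snapshot`."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = _parse_meta_value(value.strip())
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    missing = [c for c in SNAPSHOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"snapshot {path} is missing column(s): {missing}")
    t = float(frame["t_h"].iloc[0]) if len(frame) else float(meta.get("time_h", 0.0))
    return Snapshot(time=t, frame=frame, meta=meta)


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
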