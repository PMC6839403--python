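"""Contact-gated stochastic inhibition and recovery via the next reaction method.

Each susceptible target cell in contact with at least one inhibitor carries a
pending INHIBITION reaction with propensity ``eta * k`` (k = number of
contacting inhibitors); each inhibited target with no inhibitor contact
carries a pending RECOVERY reaction at rate ``mu``. Putative firing times are
kept in an indexed priority queue; when a propensity changes the remaining
waiting time is rescaled by ``a_old / a_new`` (the next-reaction-method
update, which preserves exactness without redrawing), and reactions whose
propensity drops to zero are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from cdisim.cells import CellType
from cdisim.geometry import ContactGraph

logger = logging.getLogger(__name__)


class ReactionKind(IntEnum):
    INHIBITION = 0
    RECOVERY = 1


@dataclass
class CdiParams:
    """Rates of the contact-dependent inhibition system.

    eta : inhibition rate, h^-1 per contacting inhibitor cell.
    delta : toxicity, fractional growth-rate reduction of inhibited targets.
    mu : recovery rate, h^-1, active while an inhibited target has no
        inhibitor contact.
    beta : cost, fractional growth-rate reduction of inhibitor cells.
    """

    eta: float = 0.0
    delta: float = 0.0
    mu: float = 0.01
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("inhibition rate eta must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("toxicity delta must be in [0, 1]")
        if self.mu < 0:
            raise ValueError("recovery rate mu must be >= 0")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("cost beta must be in [0, 1)")


@dataclass(order=True)
class PendingReaction:
    """A scheduled stochastic event with its putative firing time."""

    tau: float  # putative firing time, h
    kind: ReactionKind = field(compare=False)
    cell_id: int = field(compare=False)
    rate: float = field(compare=False)  # propensity a, h^-1

    @property
    def key(self) -> tuple[int, ReactionKind]:
        return (self.cell_id, self.kind)


class DuplicateReactionError(RuntimeError):
    """At most one pending reaction per (cell, kind) is allowed."""


class StaleReactionError(RuntimeError):
    """A reaction fired for a cell id that no longer exists."""


class ReactionQueue:
    """Indexed binary min-heap of pending reactions keyed by putative time.

    Supports O(log n) push, pop, removal and time-rescaling by key
    ``(cell_id, kind)``. Iteration order of :meth:`keys` is insertion order
    (deterministic).
    """

    def __init__(self) -> None:
        self._heap: list[PendingReaction] = []
        self._pos: dict[tuple[int, ReactionKind], int] = {}

    def __len__(self) -> int:
        return len(self._heap)

    def __contains__(self, key: tuple[int, ReactionKind]) -> bool:
        return key in self._pos

    def get(self, key: tuple[int, ReactionKind]) -> PendingReaction | None:
        pos = self._pos.get(key)
        return self._heap[pos] if pos is not None else None

    def keys(self):
        return list(self._pos.keys())

    def push(self, reaction: PendingReaction) -> None:
        if reaction.key in self._pos:
            raise DuplicateReactionError(
                f"pending reaction already exists for {reaction.key}")
        self._heap.append(reaction)
        self._pos[reaction.key] = len(self._heap) - 1
        self._sift_up(len(self._heap) - 1)

    def peek(self) -> PendingReaction | None:
        return self._heap[0] if self._heap else None

    def pop(self) -> PendingReaction:
        if not self._heap:
            raise IndexError("pop from empty reaction queue")
        top = self._heap[0]
        self._remove_at(0)
        return top

    def remove(self, key: tuple[int, ReactionKind]) -> PendingReaction | None:
        pos = self._pos.get(key)
        if pos is None:
            return None
        reaction = self._heap[pos]
        self._remove_at(pos)
        return reaction

    def update_time(self, key: tuple[int, ReactionKind], tau: float,
                    rate: float) -> None:
        pos = self._pos[key]
        r = self._heap[pos]
        old_tau = r.tau
        r.tau = tau
        r.rate = rate
        if tau < old_tau:
            self._sift_up(pos)
        else:
            self._sift_down(pos)

    # heap plumbing -------------------------------------------------------

    def _remove_at(self, pos: int) -> None:
        key = self._heap[pos].key
        last = self._heap.pop()
        del self._pos[key]
        if pos < len(self._heap):
            self._heap[pos] = last
            self._pos[last.key] = pos
            self._sift_up(pos)
            self._sift_down(pos)

    def _swap(self, a: int, b: int) -> None:
        self._heap[a], self._heap[b] = self._heap[b], self._heap[a]
        self._pos[self._heap[a].key] = a
        self._pos[self._heap[b].key] = b

    def _sift_up(self, pos: int) -> None:
        while pos > 0:
            parent = (pos - 1) // 2
            if self._heap[pos].tau < self._heap[parent].tau:
                self._swap(pos, parent)
                pos = parent
            else:
                break

    def _sift_down(self, pos: int) -> None:
        n = len(self._heap)
        while True:
            child = 2 * pos + 1
            if child >= n:
                break
            if child + 1 < n and self._heap[child + 1].tau < self._heap[child].tau:
                child += 1
            if self._heap[child].tau < self._heap[pos].tau:
                self._swap(pos, child)
                pos = child
            else:
                break

    def check(self) -> None:
        """Validate heap order and index consistency (used by tests)."""
        for pos, r in enumerate(self._heap):
            assert self._pos[r.key] == pos
            parent = (pos - 1) // 2
            if pos > 0:
                assert self._heap[parent].tau <= r.tau
        assert len(self._pos) == len(self._heap)


def inhibitor_contact_counts(contacts: ContactGraph,
                             types: np.ndarray) -> np.ndarray:
    """Per-cell count of contacting inhibitor cells."""
    return contacts.degrees(mask=np.asarray(types) == CellType.INHIBITOR)


def inhibition_propensity(target_pos: int, contacts: ContactGraph,
                          types: np.ndarray, eta: float) -> float:
    """Propensity of the inhibition reaction for one uninhibited target:
    ``eta`` times the number of inhibitor cells currently in contact."""
    types = np.asarray(types)
    if types[target_pos] != CellType.TARGET:
        raise ValueError("inhibition propensity is defined only for "
                         "uninhibited target cells")
    return float(eta) * int(inhibitor_contact_counts(contacts, types)[target_pos])


def schedule(kind: ReactionKind, cell_id: int, rate: float, now: float,
             rng: np.random.Generator, queue: ReactionQueue) -> PendingReaction:
    """Draw a putative firing time ``now + E/rate`` (E ~ Exponential(1)) and
    enqueue the reaction."""
    if rate <= 0:
        raise ValueError("cannot schedule a reaction with zero propensity")
    tau = now + rng.exponential() / rate
    reaction = PendingReaction(tau=tau, kind=kind, cell_id=int(cell_id),
                               rate=float(rate))
    queue.push(reaction)
    return reaction


def rescale(queue: ReactionQueue, key: tuple[int, ReactionKind],
            new_rate: float, now: float) -> PendingReaction | None:
    """Adjust a pending reaction to a changed propensity.

    The remaining waiting time is scaled by ``a_old / a_new`` so that the
    originally drawn exponential quantile is preserved; a zero new propensity
    removes the reaction. Returns the updated reaction, or None if removed.
    """
    pending = queue.get(key)
    if pending is None:
        raise KeyError(f"no pending reaction for {key}")
    if new_rate <= 0:
        queue.remove(key)
        return None
    if now > pending.tau:
        raise ValueError("cannot rescale a reaction past its firing time")
    tau = now + (pending.rate / new_rate) * (pending.tau - now)
    queue.update_time(key, tau, new_rate)
    return queue.get(key)


def sync_reactions(contacts: ContactGraph, ids: np.ndarray, types: np.ndarray,
                   queue: ReactionQueue, params: CdiParams, now: float,
                   rng: np.random.Generator) -> None:
    """Reconcile the pending-reaction queue with the current contact graph.

    After the call: every uninhibited target with >= 1 inhibitor contact has
    exactly one INHIBITION reaction at propensity ``eta * k`` (scheduled
    fresh on first contact, rescaled when the contact count changed, removed
    when contact is lost); every inhibited target with no inhibitor contact
    has exactly one RECOVERY reaction at rate ``mu`` (removed when contact is
    re-established); no other reactions remain (stale entries for divided or
    re-typed cells are dropped).
    """
    ids = np.asarray(ids)
    types = np.asarray(types)
    counts = inhibitor_contact_counts(contacts, types)

    inhibition, recovery = ReactionKind.INHIBITION, ReactionKind.RECOVERY
    desired: dict[tuple[int, ReactionKind], float] = {}
    if params.eta > 0:
        eligible = np.nonzero((types == CellType.TARGET) & (counts > 0))[0]
        for pos in eligible:
            desired[(int(ids[pos]), inhibition)] = params.eta * int(counts[pos])
    if params.mu > 0:
        eligible = np.nonzero((types == CellType.INHIBITED_TARGET)
                              & (counts == 0))[0]
        for pos in eligible:
            desired[(int(ids[pos]), recovery)] = params.mu

    for key in queue.keys():
        if key not in desired:
            queue.remove(key)
    for key, rate in desired.items():
        pending = queue.get(key)
        if pending is None:
            schedule(key[1], key[0], rate, now, rng, queue)
        elif pending.rate != rate:
            rescale(queue, key, rate, now)


def fire(reaction: PendingReaction, id_to_pos: dict[int, int],
         types: np.ndarray) -> int | None:
    """Apply a fired reaction to the cell-type array, in place.

    INHIBITION turns a TARGET into an INHIBITED_TARGET; RECOVERY turns an
    INHIBITED_TARGET back into a TARGET. Returns the positional index of the
    affected cell, or None when the reaction is stale (cell id vanished, e.g.
    through division), in which case it is dropped with a log message.
    """
    pos = id_to_pos.get(reaction.cell_id)
    if pos is None:
        logger.warning("dropping stale reaction %s for vanished cell %d",
                       reaction.kind.name, reaction.cell_id)
        return None
    if reaction.kind == ReactionKind.INHIBITION:
        if types[pos] != CellType.TARGET:
            logger.warning("dropping stale INHIBITION for cell %d in state %s",
                           reaction.cell_id, CellType(types[pos]).name)
            return None
        types[pos] = CellType.INHIBITED_TARGET
    elif reaction.kind == ReactionKind.RECOVERY:
        if types[pos] != CellType.INHIBITED_TARGET:
            logger.warning("dropping stale RECOVERY for cell %d in state %s",
                           reaction.cell_id, CellType(types[pos]).name)
            return None
        types[pos] = CellType.TARGET
    return pos
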