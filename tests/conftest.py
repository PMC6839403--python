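"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cdisim.cells import CellCollection, CellType


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_collection(rng: np.random.Generator, n: int, box: float = 30.0,
                      radius: float = 0.4) -> CellCollection:
    """Random capsule population in a square box (positions dense enough
    that some pairs touch)."""
    return CellCollection(
        ids=np.arange(n, dtype=np.int64),
        parent_ids=np.full(n, -1, dtype=np.int64),
        centers=rng.uniform(-box / 2, box / 2, size=(n, 2)),
        angles=rng.uniform(0, 2 * np.pi, n),
        lengths=rng.uniform(0.5, 4.0, n),
        radii=np.full(n, radius),
        types=rng.integers(0, 3, n).astype(np.int8),
        target_lengths=rng.uniform(3.0, 4.0, n),
    )


def segment_endpoints(coll: CellCollection):
    u = coll.axes()
    h = (0.5 * coll.lengths)[:, None]
    return coll.centers - h * u, coll.centers + h * u


def brute_force_segment_distance(p1, q1, p2, q2, samples: int = 400) -> float:
    """Dense-sampling estimate of the minimum distance between two segments
    (independent oracle; refine with more samples for tighter tolerance)."""
    t = np.linspace(0.0, 1.0, samples)
    a = p1[None, :] + t[:, None] * (q1 - p1)[None, :]
    b = p2[None, :] + t[:, None] * (q2 - p2)[None, :]
    best = np.inf
    for chunk in np.array_split(a, max(1, samples // 50)):
        d = np.hypot(chunk[:, None, 0] - b[None, :, 0],
                     chunk[:, None, 1] - b[None, :, 1])
        best = min(best, float(d.min()))
    return best


def brute_force_contacts(coll: CellCollection, tol: float) -> set[tuple[int, int]]:
    """All-pairs O(n^2) contact oracle using scipy-free analytic segment
    distance via per-pair quadratic minimization on a fine grid + refinement.

    Uses a dense parameter grid fine enough for the tolerance used in tests;
    independent of the package's closest-point routine.
    """
    p, q = segment_endpoints(coll)
    n = coll.n
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            # generous prefilter to keep the oracle fast but exact for
            # decisions at the tolerance used in tests
            cc = np.hypot(*(coll.centers[i] - coll.centers[j]))
            reach = (0.5 * coll.lengths[i] + 0.5 * coll.lengths[j]
                     + coll.radii[i] + coll.radii[j] + tol)
            if cc > reach + 1.0:
                continue
            d = _exact_segment_distance(p[i], q[i], p[j], q[j])
            if d - (coll.radii[i] + coll.radii[j]) <= tol:
                out.add((i, j))
    return out


def _exact_segment_distance(p1, q1, p2, q2) -> float:
    """Closed-form minimum distance between 2D segments via the four
    point-segment distances plus an intersection test (a classical identity:
    for non-intersecting segments the minimum is attained at an endpoint)."""
    if _segments_intersect(p1, q1, p2, q2):
        return 0.0
    return min(_point_segment_distance(p1, p2, q2),
               _point_segment_distance(q1, p2, q2),
               _point_segment_distance(p2, p1, q1),
               _point_segment_distance(q2, p1, q1))


def _point_segment_distance(pt, a, b) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(pt - a)))
    t = np.clip(float((pt - a) @ ab) / denom, 0.0, 1.0)
    return float(np.hypot(*(pt - (a + t * ab))))


def _segments_intersect(p1, q1, p2, q2) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-15 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return (min(a[0], b[0]) - 1e-15 <= c[0] <= max(a[0], b[0]) + 1e-15
                and min(a[1], b[1]) - 1e-15 <= c[1] <= max(a[1], b[1]) + 1e-15)

    o1, o2 = orient(p1, q1, p2), orient(p1, q1, q2)
    o3, o4 = orient(p2, q2, p1), orient(p2, q2, q1)
    if o1 != o2 and o3 != o4:
        return True
    for (a, b, c, o) in [(p1, q1, p2, o1), (p1, q1, q2, o2),
                         (p2, q2, p1, o3), (p2, q2, q1, o4)]:
        if o == 0 and on_seg(a, b, c):
            return True
    return False
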