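"""Colony-composition statistics: neighbor index, radial annulus profiles,
sector counting/sizing via circular smoothing, and relative fitness.

All operations consume snapshot tables in the engine schema (or equivalent
DataFrames) and treat inhibited targets as members of the target strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from cdisim.geometry import ContactGraph

DEFAULT_ANNULUS_WIDTH = 20.0  # um
SMOOTHING_SIGMA = 3.0  # bins
MIN_BINS = 16


class UndefinedStatisticError(ValueError):
    """A statistic's preconditions (e.g. nonzero counts) are not met."""


# ---------------------------------------------------------------------------
# scalar formulas

def neighbor_index(i_t0: float, t_t0: float, i_tend: float, t_tend: float) -> float:
    """log2 change of the inhibitor:target ratio at the contact interface,
    ``log2(I_end/T_end) - log2(I_0/T_0)``.

    Positive values mean proportionally more inhibitors at the interface at
    the endpoint. All four counts must be positive.
    """
    counts = (i_t0, t_t0, i_tend, t_tend)
    if any(c <= 0 for c in counts):
        raise UndefinedStatisticError(
            f"neighbor index undefined for zero counts: {counts}")
    return float(np.log2(i_tend / t_tend) - np.log2(i_t0 / t_t0))


def relative_fitness(s1_t0: float, s1_tend: float, s2_t0: float,
                     s2_tend: float) -> float:
    """Ratio of log fold-changes, ``ln(S1_end/S1_0) / ln(S2_end/S2_0)``."""
    if min(s1_t0, s1_tend, s2_t0, s2_tend) <= 0:
        raise UndefinedStatisticError("relative fitness requires positive counts")
    denom = np.log(s2_tend / s2_t0)
    if denom == 0:
        raise UndefinedStatisticError(
            "relative fitness undefined: reference strain did not grow")
    return float(np.log(s1_tend / s1_t0) / denom)


# ---------------------------------------------------------------------------
# interface counts

def _strain_codes(frame: pd.DataFrame) -> np.ndarray:
    """1 for inhibitors, 0 for targets (inhibited targets are targets)."""
    if "cell_type" in frame.columns:
        return (frame["cell_type"].to_numpy() == "inhibitor").astype(np.int8)
    raise ValueError("snapshot table lacks a 'cell_type' column")


def interface_counts(frame: pd.DataFrame,
                     contacts: ContactGraph) -> tuple[int, int]:
    """Count cells at the inter-strain contact interface.

    Returns ``(I, T)``: inhibitors touching at least one target cell, and
    targets (including inhibited targets) touching at least one inhibitor.
    ``contacts`` must be built for the same row order as ``frame``.
    """
    strain = _strain_codes(frame)
    if contacts.n_cells != len(strain):
        raise ValueError("contact graph size does not match the table")
    cross_deg = contacts.degrees(mask=strain == 1)  # inhibitor neighbors
    t_at_interface = int(np.sum((strain == 0) & (cross_deg > 0)))
    cross_deg_t = contacts.degrees(mask=strain == 0)  # target neighbors
    i_at_interface = int(np.sum((strain == 1) & (cross_deg_t > 0)))
    return i_at_interface, t_at_interface


# ---------------------------------------------------------------------------
# radial annuli and sectors

@dataclass
class AnnulusSummary:
    """Composition and sector statistics of one annulus."""

    index: int
    r_inner: float
    r_outer: float
    n_inhibitor: int
    n_target: int  # includes inhibited targets
    strip: np.ndarray | None = None  # fixed-point binary strip (1=inhibitor)
    n_sectors: int | None = None
    largest_inhibitor_rad: float | None = None
    largest_target_rad: float | None = None
    too_sparse: bool = False

    @property
    def n_cells(self) -> int:
        return self.n_inhibitor + self.n_target

    @property
    def inhibitor_ratio(self) -> float:
        if self.n_cells == 0:
            return float("nan")
        return self.n_inhibitor / self.n_cells


def colony_center(frame: pd.DataFrame) -> np.ndarray:
    """Colony center: centroid of all cell positions."""
    if len(frame) == 0:
        raise ValueError("cannot locate the center of an empty colony")
    return frame[["x_um", "y_um"]].to_numpy().mean(axis=0)


def radial_profile(frame: pd.DataFrame,
                   annulus_width: float = DEFAULT_ANNULUS_WIDTH,
                   center: np.ndarray | None = None,
                   sectors: bool = False) -> list[AnnulusSummary]:
    """Split the colony into concentric annuli of constant width and report
    the strain composition (and, optionally, sector statistics) of each.

    Every cell is assigned to annulus ``floor(distance / width)`` measured
    from the colony centroid; the sum of per-annulus counts equals the total
    cell count.
    """
    if annulus_width <= 0:
        raise ValueError("annulus width must be > 0")
    if len(frame) == 0:
        raise ValueError("cannot profile an empty snapshot")
    if center is None:
        center = colony_center(frame)
    xy = frame[["x_um", "y_um"]].to_numpy() - center
    dist = np.hypot(xy[:, 0], xy[:, 1])
    strain = _strain_codes(frame)
    idx = np.floor(dist / annulus_width).astype(int)
    n_annuli = int(idx.max()) + 1

    diam = 2.0 * frame["radius_um"].to_numpy() if "radius_um" in frame.columns \
        else np.full(len(frame), 0.8)
    angles = np.arctan2(xy[:, 1], xy[:, 0])

    out = []
    for a in range(n_annuli):
        in_a = idx == a
        n_i = int(strain[in_a].sum())
        n_t = int(in_a.sum()) - n_i
        summary = AnnulusSummary(index=a, r_inner=a * annulus_width,
                                 r_outer=(a + 1) * annulus_width,
                                 n_inhibitor=n_i, n_target=n_t)
        if sectors and summary.n_cells > 0:
            r_mid = 0.5 * (summary.r_inner + summary.r_outer)
            strip = sector_strip(angles[in_a], strain[in_a], r_mid,
                                 float(diam[in_a].mean()))
            if strip is None:
                summary.too_sparse = True
            else:
                summary.strip = strip
                summary.n_sectors = count_sectors(strip)
                sizes = sector_sizes(strip)
                summary.largest_inhibitor_rad = sizes["largest_inhibitor_rad"]
                summary.largest_target_rad = sizes["largest_target_rad"]
        out.append(summary)
    return out


def _smooth_to_fixed_point(values: np.ndarray, sigma: float = SMOOTHING_SIGMA,
                           max_rounds: int = 200) -> np.ndarray:
    """Iterate circular Gaussian smoothing + 0.5-threshold binarization until
    the binarized strip is a fixed point (ties binarize to inhibitor)."""
    x = np.asarray(values, dtype=float)
    prev = None
    for _ in range(max_rounds):
        smoothed = gaussian_filter1d(x, sigma=sigma, mode="wrap")
        binary = (smoothed >= 0.5).astype(np.int8)
        if prev is not None and np.array_equal(binary, prev):
            return binary
        prev = binary
        x = binary.astype(float)
    return prev  # cycle guard; in practice a fixed point is reached quickly


def sector_strip(angles: np.ndarray, strain: np.ndarray, r_mid: float,
                 mean_diameter: float,
                 n_bins: int | None = None) -> np.ndarray | None:
    """Discretize one annulus into a circular binary strip of cell types.

    The angular axis is split into ``max(16, circumference / mean cell
    diameter)`` bins; each occupied bin takes the mean strain code of its
    cells (inhibitor = 1), empty bins inherit the value of the nearest
    occupied bin (circularly). The strip is then smoothed to a fixed point
    (sigma = 3 bins), which removes all single-bin runs. Returns None when
    fewer than 3 bins are occupied (too sparse to call sectors).
    """
    angles = np.asarray(angles, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if n_bins is None:
        if mean_diameter <= 0:
            raise ValueError("mean cell diameter must be > 0")
        n_bins = max(MIN_BINS, int(round(2.0 * np.pi * r_mid / mean_diameter)))
    wrapped = np.mod(angles, 2.0 * np.pi)
    which = np.minimum((wrapped / (2.0 * np.pi) * n_bins).astype(int),
                       n_bins - 1)
    sums = np.bincount(which, weights=strain, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < 3:
        return None
    values = np.zeros(n_bins)
    values[occupied] = sums[occupied] / counts[occupied]
    if not occupied.all():
        values = _fill_circular_nearest(values, occupied)
    return _smooth_to_fixed_point(values)


def _fill_circular_nearest(values: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Assign each empty bin the value of its circularly nearest occupied bin
    (ties go to the counter-clockwise neighbor)."""
    n = len(values)
    occ_idx = np.nonzero(occupied)[0]
    empty_idx = np.nonzero(~occupied)[0]
    # distances on the circle from each empty bin to each occupied bin
    diff = np.abs(empty_idx[:, None] - occ_idx[None, :])
    circ = np.minimum(diff, n - diff)
    nearest = occ_idx[np.argmin(circ, axis=1)]
    out = values.copy()
    out[empty_idx] = values[nearest]
    return out


def count_sectors(strip: np.ndarray) -> int:
    """Number of inhibitor-to-target transitions around the circular strip.

    On a circle this equals both the number of target sectors and the number
    of inhibitor sectors; a homogeneous strip has zero.
    """
    s = np.asarray(strip, dtype=int)
    nxt = np.roll(s, -1)
    return int(np.sum((s == 1) & (nxt == 0)))


def _run_lengths_circular(strip: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (value, length) runs of a circular strip; a homogeneous strip
    yields one run spanning everything."""
    s = np.asarray(strip, dtype=int)
    n = len(s)
    change = np.nonzero(s != np.roll(s, 1))[0]
    if len(change) == 0:
        return [(int(s[0]), n)]
    runs = []
    for k, start in enumerate(change):
        end = change[(k + 1) % len(change)]
        length = (end - start) % n or n
        runs.append((int(s[start]), length))
    return runs


def sector_sizes(strip: np.ndarray,
                 normalization_bins: int | None = None) -> dict:
    """Angular sizes of the largest sector of each strain, in radians.

    Each maximal run of ``b`` bins spans ``b * 2*pi / n_norm`` radians, where
    ``n_norm`` defaults to the strip's own bin count; passing the bin count
    of the largest annulus analyzed normalizes all strips to a common scale.
    """
    s = np.asarray(strip, dtype=int)
    n = len(s)
    n_norm = n if normalization_bins is None else int(normalization_bins)
    per_bin = 2.0 * np.pi / n_norm
    runs = _run_lengths_circular(s)
    largest = {0: 0, 1: 0}
    for value, length in runs:
        largest[value] = max(largest[value], length)
    return {
        "largest_inhibitor_rad": largest[1] * per_bin,
        "largest_target_rad": largest[0] * per_bin,
        "normalization_bins": n_norm,
        "bin_width_rad": per_bin,
    }


# ---------------------------------------------------------------------------
# tabular export

def profile_to_frame(profile: list[AnnulusSummary]) -> pd.DataFrame:
    """Per-annulus summary table in the documented TSV schema."""
    rows = []
    for a in profile:
        rows.append({
            "annulus": a.index,
            "r_in_um": a.r_inner,
            "r_out_um": a.r_outer,
            "n_inhib": a.n_inhibitor,
            "n_target": a.n_target,
            "ratio": a.inhibitor_ratio,
            "n_sectors": a.n_sectors if a.n_sectors is not None else np.nan,
            "largest_target_rad": (a.largest_target_rad
                                   if a.largest_target_rad is not None else np.nan),
            "largest_inhib_rad": (a.largest_inhibitor_rad
                                  if a.largest_inhibitor_rad is not None else np.nan),
        })
    return pd.DataFrame(rows)


def summarize_run(frame: pd.DataFrame, annulus_width: float = DEFAULT_ANNULUS_WIDTH,
                  t0_frame: pd.DataFrame | None = None,
                  contacts=None, t0_contacts=None) -> dict:
    """Run-level JSON-ready summary: final composition, and the neighbor
    index when both endpoint snapshots (with contact graphs) are supplied."""
    strain = _strain_codes(frame)
    n = len(frame)
    out = {
        "n_cells": int(n),
        "n_inhibitor": int(strain.sum()),
        "n_target": int(n - strain.sum()),
        "n_inhibited": int(frame["inhibited"].sum()) if "inhibited" in frame else 0,
        "inhibitor_proportion": float(strain.mean()) if n else float("nan"),
    }
    if t0_frame is not None and contacts is not None and t0_contacts is not None:
        i0, t0 = interface_counts(t0_frame, t0_contacts)
        i1, t1 = interface_counts(frame, contacts)
        try:
            out["neighbor_index"] = neighbor_index(i0, t0, i1, t1)
        except UndefinedStatisticError:
            out["neighbor_index"] = None
        out["interface_counts"] = {"t0": [i0, t0], "tend": [i1, t1]}
    return out
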