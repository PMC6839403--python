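"""Static plot export for snapshots and annulus profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from cdisim.analysis import AnnulusSummary

_COLORS = {"target": "#e08214", "inhibitor": "#2166ac", "inhibited": "#b2182b"}


def plot_colony(frame, path: str | Path, max_cells: int = 250_000) -> None:
    """Scatter of cell positions colored by type (inhibited targets red)."""
    fig, ax = plt.subplots(figsize=(6, 6))
    sub = frame if len(frame) <= max_cells else frame.sample(max_cells, random_state=0)
    inhibited = sub["inhibited"].to_numpy().astype(bool)
    strain = sub["cell_type"].to_numpy()
    color = np.where(inhibited, _COLORS["inhibited"],
                     np.where(strain == "inhibitor", _COLORS["inhibitor"],
                              _COLORS["target"]))
    ax.scatter(sub["x_um"], sub["y_um"], s=2, c=color, linewidths=0)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_radial_ratio(profile: list[AnnulusSummary], path: str | Path,
                      inoculum_radius: float | None = None) -> None:
    """Inhibitor ratio per annulus against annulus mid-radius."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    r = [0.5 * (a.r_inner + a.r_outer) for a in profile if a.n_cells > 0]
    ratio = [a.inhibitor_ratio for a in profile if a.n_cells > 0]
    ax.plot(r, ratio, marker="o", ms=3)
    ax.axhline(0.5, ls="--", c="gray", lw=0.8)
    if inoculum_radius is not None:
        ax.axvline(inoculum_radius, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("radius (μm)")
    ax.set_ylabel("inhibitor ratio I/(I+T)")
    ax.set_ylim(-0.02, 1.02)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_sector_counts(profile: list[AnnulusSummary], path: str | Path) -> None:
    """Number of sectors per annulus against radius."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    pts = [(0.5 * (a.r_inner + a.r_outer), a.n_sectors)
           for a in profile if a.n_sectors is not None]
    if pts:
        r, ns = zip(*pts)
        ax.plot(r, ns, marker="o", ms=3)
    ax.set_xlabel("radius (μm)")
    ax.set_ylabel("number of sectors")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_sector_fan(profile: list[AnnulusSummary], path: str | Path) -> None:
    """Fan plot of the binary sector strips across annuli (angle vs radius)."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for a in profile:
        if a.strip is None:
            continue
        n = len(a.strip)
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        width = 2 * np.pi / n
        colors = [(_COLORS["inhibitor"] if v else _COLORS["target"])
                  for v in a.strip]
        ax.bar(theta, height=a.r_outer - a.r_inner, width=width,
               bottom=a.r_inner, color=colors, align="edge", linewidth=0)
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
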