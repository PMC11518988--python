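"""Plotting helpers (matplotlib)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt

from .cellmap import CellMap
from .networks import CellNetwork

_PHENOTYPE_COLORS = {"T": "tab:green", "T_CD8": "tab:olive", "B": "tab:blue",
                     "TREG": "tab:purple", "OTHER": "0.8"}


def plot_cellmap(cellmap: CellMap, networks: Sequence[CellNetwork] = (),
                 ax: "plt.Axes | None" = None) -> "plt.Axes":
    """Scatter a cell map (um coordinates, y down) with network hulls."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for phen, sub in cellmap.cells.groupby("phenotype"):
        ax.scatter(sub["x_um"], sub["y_um"], s=4,
                   color=_PHENOTYPE_COLORS.get(phen, "0.5"), label=phen)
    for net in networks:
        if net.hull.geom_type == "Polygon":
            x, y = net.hull.exterior.xy
            ax.plot(x, y, color="crimson", lw=1)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{cellmap.sample_id} ({cellmap.group}), "
                 f"{cellmap.tissue_area_mm2:.2f} mm$^2$")
    ax.legend(loc="upper right", fontsize=7, markerscale=2)
    return ax
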