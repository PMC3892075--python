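"""Presentation-only polar (bull's-eye) map of 17-segment values."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle, Wedge

__all__ = ["polar_map"]

# (inner radius, outer radius, sector count, start offset deg) per ring.
_RINGS = [
    (0.75, 1.0, 6, -30.0),   # basal 1-6
    (0.5, 0.75, 6, -30.0),   # mid 7-12
    (0.25, 0.5, 4, -45.0),   # apical 13-16
]


def polar_map(values, title: str = "", path=None, cmap: str = "viridis",
              vmin: float = 0.0, vmax: float = 100.0):
    """Render 17 segmental values as a bull's-eye plot (apex at centre).

    Angles follow the package convention: anterior at 12 o'clock, septal to
    the left, proceeding anterior -> septal -> inferior -> lateral.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (17,):
        raise ValueError("expected 17 segmental values")
    fig, ax = plt.subplots(figsize=(4, 4))
    norm = plt.Normalize(vmin, vmax)
    mapper = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    seg = 0
    for r0, r1, n_sec, offset in _RINGS:
        span = 360.0 / n_sec
        for i in range(n_sec):
            # matplotlib angles are CCW from +x; put anterior (theta=0) at
            # 12 o'clock with increasing theta to the left (septal).
            theta0 = 90.0 + offset + i * span
            ax.add_patch(
                Wedge((0, 0), r1, theta0, theta0 + span, width=r1 - r0,
                      facecolor=mapper.to_rgba(values[seg]), edgecolor="w")
            )
            seg += 1
    ax.add_patch(Circle((0, 0), 0.25, facecolor=mapper.to_rgba(values[16]),
                        edgecolor="w"))
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(mapper, ax=ax, fraction=0.046)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
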