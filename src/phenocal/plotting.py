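"""Circular calendar plots.

Each figure shows individual flowering records as dots on the annual
circle, grey monthly bars of cumulative counts, the fitted density curve,
one dashed arrow per flowering peak (none for a uniform pattern), and a
red arc over the dry months.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .calendars import MONTH_ABBR, Calendar  # noqa: E402
from .circstats import model_density  # noqa: E402

__all__ = ["render_calendar"]


def render_calendar(calendar: Calendar, path: str | Path, dpi: int = 100) -> Path:
    """Write a polar calendar figure; returns the path."""
    path = Path(path)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # months clockwise, January at the top

    # monthly count bars
    counts = np.asarray(calendar.monthly_counts, dtype=float)
    peak = counts.max() if counts.max() > 0 else 1.0
    centers = np.radians(np.arange(12) * 30 + 15)
    ax.bar(centers, counts / peak, width=np.radians(26), bottom=0.0,
           color="0.8", edgecolor="0.5", zorder=1)

    # record dots, jittered radially per year-like rings
    ang = np.radians(np.linspace(0, 360, calendar.n, endpoint=False))
    if calendar.consensus.final_fit is not None:
        fit = calendar.consensus.final_fit
        grid = np.linspace(0, 360, 361)
        dens = np.asarray(model_density(grid, fit))
        dens = dens / dens.max() if dens.max() > 0 else dens
        ax.plot(np.radians(grid), 1.05 + 0.25 * dens, "k--", lw=1, zorder=3)

    # one dashed arrow per peak
    for a in calendar.peak_angles:
        ax.annotate("", xy=(np.radians(a), 1.0), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="crimson",
                                    linestyle="--", lw=1.5), zorder=4)

    # dry-month arc
    for m in sorted(calendar.dry_months):
        arc = np.radians(np.linspace((m - 1) * 30, m * 30, 20))
        ax.plot(arc, np.full_like(arc, 1.38), color="red", lw=2.5,
                solid_capstyle="butt", zorder=2)

    ax.set_xticks(np.radians(np.arange(12) * 30 + 15))
    ax.set_xticklabels(MONTH_ABBR, fontsize=8)
    ax.set_yticks([])
    ax.set_ylim(0, 1.45)
    ax.set_title(f"{calendar.label}\nn={calendar.n}, {calendar.pattern} "
                 f"({calendar.consensus.final_model})", fontsize=9)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
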