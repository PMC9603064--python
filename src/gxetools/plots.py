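"""Optional SVG rendering of the four GGE biplot views.

Images are a convenience; all analysis surfaces are the geometry objects in
:mod:`gxetools.gge`.  Requires matplotlib.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .gge import (
    GgeResult,
    ideal_point_ranking,
    mean_vs_stability,
    which_won_where,
)


def biplot_views(result: GgeResult, path) -> Path:
    """Write a 2x2 SVG: tissue relationships, which-won-where, mean vs
    stability, and concentric circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 10))
    gp = result.gene_scores[:, :2]
    tp = result.tissue_scores[:, :2]

    def base(ax, title):
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        for (x, y), name in zip(gp, result.genes):
            ax.plot(x, y, "o", color="tab:red")
            ax.annotate(name, (x, y), fontsize=8, color="tab:red")
        ax.set_title(title, fontsize=10)
        ax.set_aspect("equal")

    # A: tissue vectors
    ax = axes[0, 0]
    base(ax, "relationship among tissues")
    for (x, y), name in zip(tp, result.tissues):
        ax.plot([0, x], [0, y], "-", color="tab:blue", lw=0.8)
        ax.annotate(name, (x, y), fontsize=7, color="tab:blue")

    # B: which-won-where
    ax = axes[0, 1]
    base(ax, "which-won-where")
    for (x, y), name in zip(tp, result.tissues):
        ax.plot(x, y, "s", ms=3, color="tab:blue")
        ax.annotate(name, (x, y), fontsize=7, color="tab:blue")
    sa = which_won_where(result)
    hull_pts = np.array([gp[result.genes.index(g)] for g in sa.hull])
    if len(hull_pts) >= 2:
        closed = np.vstack([hull_pts, hull_pts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], "-", color="tab:red", lw=1)
    rmax = 1.2 * max(np.abs(gp).max(), np.abs(tp).max())
    for ang in sa.boundary_angles:
        ax.plot([0, rmax * math.cos(ang)], [0, rmax * math.sin(ang)],
                "--", color="0.5", lw=0.8)

    # C: mean vs stability
    ax = axes[1, 0]
    base(ax, "mean expression vs stability")
    ms = mean_vs_stability(result)
    a = ms.axis
    rmax = 1.2 * max(np.abs(gp).max(), np.abs(tp).max())
    ax.plot([-rmax * a[0], rmax * a[0]], [-rmax * a[1], rmax * a[1]],
            "-", color="0.3", lw=1)
    for (x, y) in gp:
        proj = (np.array([x, y]) @ a) * a
        ax.plot([x, proj[0]], [y, proj[1]], ":", color="0.6", lw=0.8)

    # D: concentric circles around the ideal point
    ax = axes[1, 1]
    base(ax, "ideal point (concentric circles)")
    ip = ideal_point_ranking(result)
    ax.plot(*ip.ideal, "*", ms=12, color="tab:green")
    for radius in np.linspace(0, float(ip.distance.max()), 5)[1:]:
        circle = plt.Circle(ip.ideal, radius, fill=False, color="0.7", lw=0.8)
        ax.add_patch(circle)

    fig.suptitle(f"GGE biplots, temperature {result.temperature}", fontsize=12)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path
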