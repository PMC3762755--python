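"""Diagnostic plot of the contamination-filter geometry.

Reproduces the (x, y) = (log2 CT/HN, log2 CT/HM) plane with the x-axis,
the diagonal, the lambda_max contamination curve and the excluded band,
plus the per-pair dots of the requested probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contamination import FilterParams, contamination_boundary


def plot_filter_geometry(points: pd.DataFrame,
                         params: FilterParams | None = None,
                         probes: list[str] | None = None,
                         ax=None, path: str | None = None):
    """Plot dots from a ContaminationFilter ``points_`` frame.

    Parameters
    ----------
    points : long DataFrame with columns probe, x, y (one envelope's dots).
    params : filter thresholds used for the overlay curves.
    probes : optional subset of probes to show.
    ax : existing matplotlib axes; created when None.
    path : when given, the figure is saved there (PNG/SVG by extension).
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    params = params or FilterParams()
    pts = points if probes is None else points[points["probe"].isin(probes)]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))

    lo = float(np.nanmin(pts[["x", "y"]].min())) - 1 if len(pts) else -6
    hi = float(np.nanmax(pts[["x", "y"]].max())) + 1 if len(pts) else 6
    grid = np.linspace(lo, hi, 400)
    f = contamination_boundary(grid, params.lambda_max)

    ax.axhline(0, color="k", lw=0.8)
    ax.plot(grid, grid, color="k", lw=0.8, ls=":")
    ax.plot(grid, f, "r--", lw=1.2,
            label=f"contamination λ={params.lambda_max}")
    ax.fill_between(grid, np.minimum(0, f), np.maximum(0, f),
                    color="red", alpha=0.12)
    ax.axhspan(-params.min_abs_y, params.min_abs_y, color="gray", alpha=0.15)

    for probe, grp in pts.groupby("probe"):
        ax.scatter(grp["x"], grp["y"], s=14, label=None)
    ax.set_xlabel("x = log2(CT / HN)")
    ax.set_ylabel("y = log2(CT / HM)")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
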