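"""Small diagnostic plots (oxygen maps and fluctuation series)."""

from __future__ import annotations

import numpy as np

from .oxygen import OxygenField
from .tissue import TissueLayout

__all__ = ["plot_field", "plot_layout", "plot_series"]


def plot_field(field: OxygenField, ax=None, vmax=None):
    """Oxygen map in the oximetry color convention (cyan low, white high)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if ax is None:
        _, ax = plt.subplots()
    cmap = LinearSegmentedColormap.from_list("epr", ["#00b7c8", "#ffffff"])
    xmin, xmax, ymin, ymax = field.params.domain
    im = ax.imshow(field.values.T, origin="lower", cmap=cmap,
                   extent=(xmin, xmax, ymin, ymax), vmin=0.0,
                   vmax=vmax or field.params.gamma_max)
    ax.figure.colorbar(im, ax=ax, label="pO2 (mmHg)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_layout(layout: TissueLayout, params, ax=None):
    """Histology-style morphology map (vessels red, tumor purple, stroma pink)."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import EllipseCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for pts, r, color in ((layout.vessels, params.R_V, "#c0392b"),
                          (layout.tumor_cells, params.R_T, "#6c3483"),
                          (layout.stromal_cells, params.R_S, "#f5b7b1")):
        if not len(pts):
            continue
        ec = EllipseCollection(widths=2 * r, heights=2 * r, angles=0,
                               units="x", offsets=np.asarray(pts),
                               transOffset=ax.transData, facecolor=color,
                               edgecolor="none", alpha=0.9)
        ax.add_collection(ec)
    xmin, xmax, ymin, ymax = params.domain
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymin, ymax)
    ax.set_aspect("equal")
    return ax


def plot_series(times_min, measured, simulated=None, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(times_min, measured, "k-o", label="measured")
    if simulated is not None:
        ax.plot(times_min, simulated, "b^--", label="simulated")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("average pO2 (mmHg)")
    ax.legend()
    return ax
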