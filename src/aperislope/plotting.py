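"""Optional matplotlib figures: loading topographies and slope time courses.

matplotlib is imported lazily; the rest of the package works without it.
"""

from __future__ import annotations

import numpy as np

from .layout import ChannelLayout
from .reduction import ComponentModel
from .slope import SlopeMaps


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires the optional matplotlib dependency") from exc
    return plt


def plot_loading_topography(model: ComponentModel, layout: ChannelLayout, ax=None):
    """Schematic scalp maps of the retained components' rotated loadings."""
    plt = _plt()
    retained = np.flatnonzero(model.retained)
    if ax is None:
        _, axes = plt.subplots(1, max(len(retained), 1), figsize=(3 * len(retained), 3))
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
    for a, j in zip(axes, retained):
        load = model.loadings_rotated_std[:, j]
        sc = a.scatter(
            layout.positions[:, 0], layout.positions[:, 1], c=load,
            cmap="RdBu_r", vmin=-np.abs(load).max(), vmax=np.abs(load).max(),
            s=60, edgecolors="k", linewidths=0.3,
        )
        name = model.names[j] if model.names else f"comp {j + 1}"
        a.set_title(f"{name} ({model.explained_of_solution[j]:.0%})")
        a.set_aspect("equal")
        a.axis("off")
        plt.colorbar(sc, ax=a, shrink=0.7)
    return axes


def plot_slope_timecourses(
    maps: SlopeMaps, layout: ChannelLayout, regions=("frontal", "central", "occipital"),
    ax=None,
):
    """Grand-average slope time course per scalp region and condition cell."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for region in regions:
        idx = [maps.channel_labels.index(ch) for ch in layout.region_members(region)]
        grand = np.nanmean(maps.values[:, :, idx, :], axis=(0, 2))
        for j, cell in enumerate(maps.cells):
            label = f"{region} {cell[0][:1]}->{cell[1][:1]}"
            ax.plot(maps.times, grand[j], lw=0.8, label=label)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("aperiodic slope")
    ax.legend(fontsize=6, ncol=3)
    return ax
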