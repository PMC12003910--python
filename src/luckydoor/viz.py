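"""Optional scalp-topography rendering for map statistics."""

from __future__ import annotations

import numpy as np

from .group_stats import MapStatResult
from .montage import Montage


def plot_topomap(result: MapStatResult, montage: Montage, ax=None, cmap="RdBu_r"):
    """Render a differential scalp map with significant electrodes marked '+'.

    Returns the matplotlib Axes. Interpolation is a simple triangulated
    contour over the 2-D electrode positions.
    """
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    idx = [montage.index(c) for c in result.ch_names]
    pos = montage.positions[idx]
    t = np.nan_to_num(result.tvals)
    tri = mtri.Triangulation(pos[:, 0], pos[:, 1])
    vmax = max(np.abs(t).max(), 1e-6)
    tc = ax.tricontourf(tri, t, levels=21, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.scatter(pos[:, 0], pos[:, 1], s=8, c="k", zorder=3)
    sig = pos[result.sig_mask]
    if len(sig):
        ax.scatter(sig[:, 0], sig[:, 1], s=60, marker="+", c="k", zorder=4)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"{result.band} / {result.period}", fontsize=9)
    plt.colorbar(tc, ax=ax, shrink=0.7, label="t")
    return ax
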