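"""Plotting helpers: fragmentation curves and topology scatterplots."""

from __future__ import annotations

import numpy as np


def smoothed_median_trend(x, y, bandwidth: float | None = None,
                          n_points: int = 50,
                          log_x: bool = True):
    """Gaussian-weighted running median of y against x.

    The trend line drawn through per-node clustering / neighbor-degree
    scatterplots.  ``bandwidth`` is in the (possibly log-transformed)
    x units; default is a quarter of the x range.  Returns (grid,
    trend) arrays; bins with no effective weight give NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0 if log_x else np.full(x.shape, True))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite data points")
    t = np.log10(x) if log_x else x
    if bandwidth is None:
        bandwidth = max((t.max() - t.min()) / 4.0, 1e-6) / 2.0
    grid_t = np.linspace(t.min(), t.max(), n_points)
    trend = np.full(n_points, np.nan)
    for i, g in enumerate(grid_t):
        w = np.exp(-0.5 * ((t - g) / bandwidth) ** 2)
        if w.sum() < 1e-12:
            continue
        order = np.argsort(y)
        cw = np.cumsum(w[order])
        trend[i] = y[order[np.searchsorted(cw, 0.5 * cw[-1])]]
    grid = 10 ** grid_t if log_x else grid_t
    return grid, trend


def plot_fragmentation_curves(curves, labels=None, ax=None):
    """Overlay S(f) curves; the diagonal (ideal large-N limit) is dashed."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    labels = labels or [c.scheme or f"curve {i}" for i, c in enumerate(curves)]
    for curve, lab in zip(curves, labels):
        ax.plot(curve.f, curve.S, label=f"{lab} (R={curve.R:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="bisectrix")
    ax.set_xlabel("fraction of isolated nodes f")
    ax.set_ylabel("fragmentation entropy S(f)")
    ax.legend(fontsize="small")
    return ax


def plot_topology_scatter(topo, ax=None):
    """Clustering coefficient and mean neighbor degree vs node degree,
    with Gaussian-smoothed median trend lines."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    d = topo["degree"].to_numpy(dtype=float)
    pos = d > 0
    ax.scatter(d[pos], topo["clustering"].to_numpy()[pos], s=4, alpha=0.3,
               color="tab:red", label="clustering coefficient")
    gx, gy = smoothed_median_trend(d[pos], topo["clustering"].to_numpy()[pos])
    ax.plot(gx, gy, color="darkred")
    ax2 = ax.twinx()
    nd = topo["neighbor_degree"].to_numpy(dtype=float)
    ok = pos & np.isfinite(nd)
    ax2.scatter(d[ok], nd[ok], s=4, alpha=0.3, color="tab:blue",
                label="mean neighbor degree")
    gx, gy = smoothed_median_trend(d[ok], nd[ok])
    ax2.plot(gx, gy, color="darkblue")
    ax.set_xscale("log")
    ax.set_xlabel("degree")
    ax.set_ylabel("clustering coefficient")
    ax2.set_ylabel("mean neighbor degree")
    return ax
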