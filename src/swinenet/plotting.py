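"""Plot helpers: goodness-of-fit panels and network maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gof import GofReport
from .network import TradeNetwork

__all__ = ["plot_gof_panels", "plot_network_map"]

_PANEL_ORDER = ["indegree", "outdegree", "esp", "dsp", "geodesic", "triad_census"]
_PANEL_TITLES = {
    "indegree": "in-degree",
    "outdegree": "out-degree",
    "esp": "edgewise shared partners",
    "dsp": "dyadwise shared partners",
    "geodesic": "minimum geodesic distance",
    "triad_census": "triad census",
}


def plot_gof_panels(report: GofReport, path) -> None:
    """Six histogram panels: observed statistic over the simulated envelope."""
    fig, axes = plt.subplots(2, 3, figsize=(15, 8))
    for ax, name in zip(axes.ravel(), _PANEL_ORDER):
        entry = report.statistics[name]
        x = np.arange(len(entry["bins"]))
        env = entry["envelopes"]
        ax.fill_between(x, env[2.5], env[97.5], alpha=0.3, label="95% envelope")
        ax.fill_between(x, env[25.0], env[75.0], alpha=0.4, label="IQR")
        ax.plot(x, env[50.0], lw=0.8, color="gray", label="median")
        ax.plot(x, entry["observed"], lw=1.6, color="C3", label="observed")
        ax.set_title(_PANEL_TITLES[name])
        step = max(1, len(x) // 12)
        ax.set_xticks(x[::step])
        ax.set_xticklabels([str(b) for b in entry["bins"]][::step],
                           rotation=45, fontsize=7)
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(f"Goodness of fit — {report.n_sims} simulated networks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_network_map(net: TradeNetwork, path, node_size: float = 8.0) -> None:
    """Scatter of holdings at their coordinates with movement segments."""
    fig, ax = plt.subplots(figsize=(7, 7))
    xy = net.attrs[["x", "y"]]
    for u, v in net.graph.edges():
        ax.plot(
            [xy.loc[u, "x"], xy.loc[v, "x"]],
            [xy.loc[u, "y"], xy.loc[v, "y"]],
            color="steelblue", lw=0.4, alpha=0.5, zorder=1,
        )
    ax.scatter(xy["x"], xy["y"], s=node_size, c="darkred", zorder=2)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(f"{net.subset_label} network: {net.n_nodes} holdings, "
                 f"{net.n_edges} movements")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
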