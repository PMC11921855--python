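"""Basic directed network plot with a display-only edge threshold."""

from __future__ import annotations

import numpy as np

from .estimation import CLPNFit


def plot_network(fit: CLPNFit, threshold: float = 0.025, path=None, ax=None):
    """Draw the CLPN as a circular directed graph.

    Edges with |weight| below ``threshold`` (default 0.025) are hidden for
    readability only — estimation never thresholds.  Positive edges are
    blue, negative orange; width scales with |weight|.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.DiGraph()
    labels = fit.item_labels
    g.add_nodes_from(labels)
    p = len(labels)
    for i in range(p):
        for j in range(p):
            w = fit.edge_matrix[i, j]
            if abs(w) >= threshold:
                g.add_edge(labels[i], labels[j], weight=w)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    pos = nx.circular_layout(g)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="white", edgecolors="black", node_size=1800)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)])
    if weights.size:
        colors = ["tab:blue" if w > 0 else "tab:orange" for w in weights]
        widths = 1 + 8 * np.abs(weights)
        nx.draw_networkx_edges(g, pos, ax=ax, edge_color=colors, width=widths,
                               connectionstyle="arc3,rad=0.1", arrows=True, node_size=1800)
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
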