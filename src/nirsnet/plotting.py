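"""Plots for fitted results: estimated-marginal-mean interaction plots and
directed-network matrices.  Matplotlib is imported lazily so headless
pipelines never touch a display backend."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import DirectedNetwork

__all__ = ["plot_marginal_means", "plot_network_matrix"]


def plot_marginal_means(emmeans: pd.DataFrame, dv: Optional[str] = None, ax=None):
    """Error-bar plot of estimated marginal means per factor level.

    ``emmeans`` is the output of
    :func:`nirsnet.inference.estimated_marginal_means` (optionally the
    pipeline's concatenated table with a ``dv`` column to filter on).
    """
    import matplotlib.pyplot as plt

    if dv is not None and "dv" in emmeans.columns:
        emmeans = emmeans[emmeans["dv"] == dv]
    levels = emmeans[emmeans["factor"] != "cell"]
    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(levels))
    ax.errorbar(x, levels["mean"], yerr=levels["se"], fmt="o", capsize=4)
    ax.set_xticks(x)
    ax.set_xticklabels([f"{f}\n{l}" for f, l in zip(levels["factor"], levels["level"])])
    ax.set_ylabel(dv or "estimated marginal mean")
    ax.axhline(0, color="0.8", lw=0.8, zorder=0)
    return ax


def plot_network_matrix(network: DirectedNetwork, ax=None, cmap: str = "viridis"):
    """Heatmap of the band-averaged causality matrix (rows = source,
    columns = target); invalid edges are hatched out by NaN masking."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(network.edges, cmap=cmap)
    r = len(network.roi_labels)
    ax.set_xticks(range(r)); ax.set_xticklabels(network.roi_labels, rotation=45)
    ax.set_yticks(range(r)); ax.set_yticklabels(network.roi_labels)
    ax.set_xlabel("target"); ax.set_ylabel("source")
    plt.colorbar(im, ax=ax, label="band GC (nats)")
    return ax
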