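"""Basic figures: Kaplan-Meier curves, consensus CDF curves, consensus heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ConsensusResult
from .survival import SurvivalFit


def plot_km(fit: SurvivalFit, ax=None, title: str | None = None):
    """Step-function survival curves per group, annotated with the log-rank p."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, curve in fit.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(name))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(title or f"log-rank p = {fit.p:.3g}")
    return ax


def plot_consensus_cdf(result: ConsensusResult, ax=None):
    """Empirical CDFs of consensus values for every candidate k."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    iu = np.triu_indices(next(iter(result.consensus.values())).shape[0], k=1)
    grid = np.linspace(0, 1, 101)
    for k, M in result.consensus.items():
        vals = M[iu]
        vals = vals[~np.isnan(vals)]
        cdf = [(vals <= g).mean() for g in grid]
        ax.plot(grid, cdf, label=f"k={k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(frameon=False)
    ax.set_title(f"chosen k = {result.chosen_k}")
    return ax


def plot_consensus_heatmap(result: ConsensusResult, k: int | None = None, ax=None):
    """Consensus matrix at k (default: chosen k), samples ordered by label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    k = k or result.chosen_k
    M = result.consensus[k]
    order = np.argsort(result.labels.to_numpy(), kind="stable")
    im = ax.imshow(M[np.ix_(order, order)], vmin=0, vmax=1, cmap="viridis")
    ax.set_title(f"consensus matrix, k={k}")
    plt.colorbar(im, ax=ax, label="co-cluster rate")
    return ax
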