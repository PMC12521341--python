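"""Optional static rendering of sweep heat maps and solution traces."""

from __future__ import annotations

import numpy as np


def plot_heatmap(result, metric: str = "eta", ax=None, **imshow_kwargs):
    """Render one sweep metric grid as a heat map; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grids = {"eta": result.eta_grid, "drug_cost": result.drug_cost_grid,
             **result.per_drug_cost_grids}
    grid = grids[metric]
    (xname, xvals), (yname, yvals) = list(result.axes.items())
    im = ax.imshow(
        grid.T,
        origin="lower",
        aspect="auto",
        extent=(xvals[0], xvals[-1], yvals[0], yvals[-1]),
        **imshow_kwargs,
    )
    ax.set_xlabel(xname)
    ax.set_ylabel(yname)
    ax.set_title(metric)
    ax.figure.colorbar(im, ax=ax)
    return ax


def plot_solution(sol, ax=None, drug_labels=None, state_labels=None):
    """State and control traces of an optimal-control solution."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    n, m = sol.x.shape[1], sol.u.shape[1]
    state_labels = state_labels or [f"x_{i + 1}" for i in range(n)]
    drug_labels = drug_labels or [f"u_{k + 1}" for k in range(m)]
    for i in range(n):
        ax[0].plot(sol.t, sol.x[:, i], label=state_labels[i])
    for k in range(m):
        ax[1].plot(sol.t, sol.u[:, k], label=drug_labels[k])
    ax[0].set_ylabel("population")
    ax[1].set_ylabel("drug action")
    ax[1].set_xlabel("rescaled time")
    ax[1].set_ylim(-0.02, 1.02)
    for a in np.atleast_1d(ax):
        a.legend(frameon=False, fontsize="small")
    return ax
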