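"""Minimal trajectory plotting for simulation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

DEFAULT_VARS = ("BG", "GFR", "P_gc", "MAP", "K_f", "UAER")


def plot_trajectories(results: dict, variables=DEFAULT_VARS, log_uaer=True):
    """Overlay one panel per variable for a dict of {label: SimulationResult}.

    Returns the matplotlib Figure.
    """
    n = len(variables)
    ncol = min(3, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for k, var in enumerate(variables):
        ax = axes[k // ncol][k % ncol]
        for label, res in results.items():
            ax.plot(res.frame["week"], res.frame[var], label=label)
        ax.set_xlabel("week")
        ax.set_ylabel(var)
        if var == "UAER" and log_uaer:
            ax.set_yscale("log")
    axes[0][0].legend(fontsize=8)
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    return fig
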