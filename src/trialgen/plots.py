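"""Forest-style diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_balance_forest", "plot_bias_grid"]


def plot_balance_forest(records: pd.DataFrame, path=None):
    """SMD per trait and stage with 95% CI whiskers, one panel per stage."""
    stages = list(dict.fromkeys(records["stage"]))
    traits = list(dict.fromkeys(records["trait"]))
    fig, axes = plt.subplots(1, len(stages), figsize=(3.2 * len(stages), 0.28 * len(traits) + 1.5),
                             sharey=True)
    axes = np.atleast_1d(axes)
    ypos = np.arange(len(traits))[::-1]
    for ax, stage in zip(axes, stages):
        sub = records[records["stage"] == stage].set_index("trait").loc[traits]
        ax.errorbar(sub["smd"], ypos,
                    xerr=[sub["smd"] - sub["ci_low"], sub["ci_high"] - sub["smd"]],
                    fmt="o", ms=3, lw=1, color="tab:blue")
        sig = sub["significant"].to_numpy(dtype=bool)
        ax.scatter(sub["smd"][sig], ypos[sig], s=90, facecolors="none",
                   edgecolors="tab:red", label="significant")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(stage)
        ax.set_xlabel("SMD")
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels(traits, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bias_grid(grid: pd.DataFrame, path=None):
    """Residual bias (%) versus PGS–confounder r², one line per confounding
    fraction, with ±1.96·sd tolerance bands and the analytic curve dashed."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    frac_col = "b_cx" if "conf_frac" not in grid.columns else "conf_frac"
    fracs = sorted(set(np.round(grid[frac_col] ** (2 if frac_col == "b_cx" else 1), 6)))
    for frac in fracs:
        key = np.round(grid[frac_col] ** (2 if frac_col == "b_cx" else 1), 6) == frac
        sub = grid[key].sort_values("r2")
        ax.fill_between(sub["r2"], sub["tolerance_low"], sub["tolerance_high"], alpha=0.2)
        ax.plot(sub["r2"], sub["mean_bias_pct"], "o-", ms=3, label=f"conf. fraction {frac:g}")
        ax.plot(sub["r2"], sub["analytic_bias_pct"], "--", lw=0.9, color="black")
    ax.set_xlabel("PGS–confounder $r^2$")
    ax.set_ylabel("bias of $\\hat\\beta_X$ (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
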