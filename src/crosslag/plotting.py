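"""Plot helpers: bias/power surfaces, lag scatter, case-study report.

All functions write to a file path and use the non-interactive Agg
backend, so they are safe in batch pipelines.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_grid_summary", "plot_lag_scatter", "plot_wren_report"]


def plot_grid_summary(result, path, x="T"):
    """Estimate and relative-bias panels against series length (or S),
    one line per model."""
    s = result.summary
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for model, d in s.groupby("model"):
        d = d.sort_values(x)
        axes[0].plot(d[x], d["mean_b_hat"], marker="o", label=model)
        ycol = "rel_bias_pct" if d["rel_bias_defined"].all() else "abs_bias"
        axes[1].plot(d[x], d[ycol], marker="o", label=model)
    axes[0].axhline(result.b_true, color="grey", lw=0.8, ls="--")
    axes[0].set_xlabel(x)
    axes[0].set_ylabel("mean estimate of b")
    axes[1].axhline(0.0, color="grey", lw=0.8, ls="--")
    axes[1].set_xlabel(x)
    axes[1].set_ylabel("relative bias (%)")
    axes[0].set_xscale("log")
    axes[1].set_xscale("log")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_lag_scatter(panel, path, x="X", y="Y"):
    """Within-subject-centred scatter of X[t] against Y[t-1]."""
    d = panel.data.sort_values(["subject", "time"])
    g = d.groupby("subject")
    ylag = g[y].shift(1)
    ok = ((g["time"].diff() == 1).fillna(False)) & ylag.notna()
    import pandas as pd
    pairs = pd.DataFrame({"subject": d["subject"][ok],
                          "xt": d[x][ok], "ylag": ylag[ok]})
    gp = pairs.groupby("subject")
    xt = pairs["xt"] - gp["xt"].transform("mean")
    yl = pairs["ylag"] - gp["ylag"].transform("mean")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(yl, xt, s=8, alpha=0.4)
    ax.set_xlabel(f"{y}[t-1] (within-subject centred)")
    ax.set_ylabel(f"{x}[t] (within-subject centred)")
    if len(xt) > 2:
        coef = np.polyfit(yl, xt, 1)
        xs = np.linspace(yl.min(), yl.max(), 20)
        ax.plot(xs, np.polyval(coef, xs), color="firebrick", lw=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_wren_report(panel, stat_result, dyn_result, path,
                     size_range=(2, 10)):
    """Three panels: cross-lag scatter, posterior percent-effect
    histograms, and predicted productivity across group sizes."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))

    d = panel.data.sort_values(["group", "year"])
    g = d.groupby("group")
    prod_prev = g["productivity"].shift(1)
    ok = ((g["year"].diff() == 1).fillna(False)) & prod_prev.notna()
    axes[0].scatter(prod_prev[ok], d["group_size"][ok], s=10, alpha=0.4)
    axes[0].set_xlabel("productivity[t-1]")
    axes[0].set_ylabel("group size[t]")

    for res, label in ((stat_result, "static within-group"),
                       (dyn_result, "dynamical joint")):
        axes[1].hist(res.draws["percent_effect"].ravel(), bins=40,
                     alpha=0.5, density=True, label=label)
    axes[1].axvline(0.0, color="grey", lw=0.8)
    axes[1].set_xlabel("% productivity per additional member")
    axes[1].legend(fontsize=7)

    sizes = np.arange(size_range[0], size_range[1] + 1)
    ref = panel.data["group_size"].mean()
    for res, label in ((stat_result, "static"), (dyn_result, "dynamical")):
        a = res.draws["a"].mean()
        b = res.draws["b"].mean()
        axes[2].plot(sizes, np.exp(a + b * (sizes - ref)), marker="o",
                     label=label)
    axes[2].set_xlabel("group size")
    axes[2].set_ylabel("predicted productivity")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
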