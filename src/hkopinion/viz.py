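"""Optional, headless-safe plot exports.

Plotting is a side effect only: numerical outputs never depend on this
module, and matplotlib is imported lazily with the Agg backend so the
plots work without a display.
"""

from __future__ import annotations

__all__ = ["plot_trajectory", "plot_sweep"]

_SUBGROUP_COLORS = ("tab:blue", "tab:green", "tab:red", "tab:purple", "tab:orange")


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_trajectory(result, path) -> None:
    """Opinion-vs-time panel, one line per agent, coloured by subgroup."""
    if result.trajectory is None:
        raise ValueError("run was recorded final-only; nothing to plot")
    plt = _axes()
    steps = [s.t for s in result.trajectory]
    labels = result.population.subgroup_label
    fig, ax = plt.subplots(figsize=(6, 4))
    for i in range(result.population.n):
        ax.plot(
            steps,
            [s.x[i] for s in result.trajectory],
            color=_SUBGROUP_COLORS[labels[i] % len(_SUBGROUP_COLORS)],
            lw=0.6,
            alpha=0.7,
        )
    ax.set_xlabel("time step")
    ax.set_ylabel("opinion")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(records, fit, path) -> None:
    """Mean cluster count vs the swept factor, with the fitted line."""
    plt = _axes()
    xs = [r.factor_value for r in records]
    ys = [r.mean_count for r in records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(xs, ys, color="tab:blue", zorder=3, label="replicate mean")
    if fit is not None:
        ax.plot(
            xs,
            [fit.slope * x + fit.intercept for x in xs],
            color="tab:red",
            label=f"OLS: {fit.slope:.4g}·x + {fit.intercept:.4g}",
        )
        ax.legend()
    ax.set_xlabel(records[0].factor_name.replace("_", " "))
    ax.set_ylabel("mean number of final opinion clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
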