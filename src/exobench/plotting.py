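"""Presentation-only plotting of moment-angle curves (not numerically tested)."""

from __future__ import annotations

import pandas as pd


def plot_moment_angle_curves(curves: pd.DataFrame, path) -> None:
    """One panel per task, moment vs trunk inclination, colored by device."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tasks = sorted(curves["task"].unique())
    fig, axes = plt.subplots(1, len(tasks), figsize=(4 * len(tasks), 3.2),
                             sharey=True, squeeze=False)
    for ax, task in zip(axes[0], tasks):
        sub = curves[curves["task"] == task]
        for exo, g in sub.groupby("exo"):
            for branch, gb in g.groupby("branch"):
                ax.plot(gb["theta_deg"], gb["moment_Nm"],
                        lw=1.5 if branch == "flexion" else 0.8,
                        label=exo if branch == "flexion" else None)
        ax.set_title(task)
        ax.set_xlabel("trunk inclination (deg)")
    axes[0][0].set_ylabel("assistive moment (Nm)")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
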