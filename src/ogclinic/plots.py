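"""Figures: TT box plots per class and percent-change bar charts.

Requires matplotlib (optional dependency, extra ``plot``).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["tt_boxplot", "percent_change_bars"]


def tt_boxplot(tt_frame, out_path: str | Path, measure: str = "overall_tt"):
    """Box plot of a turnaround-time measure per patient class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(tt_frame["klass"].unique())
    data = [tt_frame.loc[tt_frame["klass"] == k, measure] for k in classes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=classes, showfliers=False)
    ax.set_ylabel(f"{measure.replace('_', ' ')} (min)")
    ax.set_title("Turnaround time by patient class")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


def percent_change_bars(changes: dict, out_path: str | Path,
                        title: str = "Change in median overall TT vs base case"):
    """Grouped bars of percent change per scenario (keys) and group (subkeys)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    scenarios = list(changes)
    groups = sorted({g for v in changes.values() for g in v})
    x = np.arange(len(scenarios))
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, g in enumerate(groups):
        vals = [changes[s].get(g, float("nan")) for s in scenarios]
        ax.bar(x + i * width, vals, width, label=g)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels([f"scenario {s}" for s in scenarios])
    ax.set_ylabel("% change vs base")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)
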