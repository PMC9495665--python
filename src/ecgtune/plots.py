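"""Static report figures: main effects, per-task R2 bars, box summaries.

All functions write a PNG and return the path, or return None on any
plotting failure — figures are a convenience and must never abort a
pipeline run.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_main_effects", "plot_combination_bars", "plot_distribution_boxes"]


def _save(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_main_effects(effects, path):
    """One panel per factor: level means of the response, delta in the title."""
    try:
        table = effects.table
        factors = list(dict.fromkeys(table["factor"]))
        fig, axes = plt.subplots(
            1, len(factors), figsize=(3 * len(factors), 3), sharey=True
        )
        if len(factors) == 1:
            axes = [axes]
        for ax, name in zip(axes, factors):
            sub = table[table["factor"] == name]
            ax.plot(range(len(sub)), sub["mean_response"], "o-")
            ax.set_xticks(range(len(sub)))
            ax.set_xticklabels([str(v) for v in sub["level"]], rotation=45)
            ax.set_title(f"{name}\n(delta {sub['delta'].iloc[0]:.3f})", fontsize=9)
            ax.axhline(effects.grand_mean, color="grey", lw=0.5, ls="--")
        axes[0].set_ylabel(f"mean {effects.response}")
        return _save(fig, path)
    except Exception:
        plt.close("all")
        return None


def plot_combination_bars(table, path, metric: str = "r2"):
    """Grouped bars of the best metric per task, one group per method."""
    try:
        fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(table)), 4))
        labels = table["set"] + ":" + table["inputs"] + ">" + table["output"]
        for i, (method, sub) in enumerate(table.groupby("method")):
            offs = [j + 0.35 * i for j in range(len(sub))]
            ax.bar(offs, sub[metric], width=0.35, label=method)
        ax.set_xticks(range(table["method"].nunique() and len(labels.unique())))
        ax.set_xticklabels(labels.unique(), rotation=90, fontsize=7)
        ax.set_ylabel(metric)
        ax.legend()
        return _save(fig, path)
    except Exception:
        plt.close("all")
        return None


def plot_distribution_boxes(summaries: dict, path):
    """Box-style five-number summaries of actual vs predicted traces."""
    try:
        fig, ax = plt.subplots(figsize=(2 + len(summaries), 4))
        stats = []
        for name, s in summaries.items():
            stats.append(
                {
                    "label": name,
                    "whislo": s["min"],
                    "q1": s["q1"],
                    "med": s["median"],
                    "q3": s["q3"],
                    "whishi": s["max"],
                    "fliers": [],
                }
            )
        ax.bxp(stats, showfliers=False)
        ax.set_ylabel("normalized amplitude")
        return _save(fig, path)
    except Exception:
        plt.close("all")
        return None
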