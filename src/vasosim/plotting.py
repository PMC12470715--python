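"""Optional matplotlib views of runs and metric comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_runs", "plot_metric_bars"]


def plot_runs(results, threshold: float = 85.0, path=None, title: str | None = None):
    """Overlay the generated sBP of each run; dashed line marks the threshold."""
    fig, ax = plt.subplots(figsize=(9, 4))
    for i, r in enumerate(results):
        ax.plot(np.arange(r.generated.values.size), r.generated.values,
                lw=0.8, alpha=0.7, label=f"run {i}" if len(results) <= 5 else None)
    if results:
        ax.plot(np.arange(results[0].baseline.values.size),
                results[0].baseline.values, color="k", lw=1.2, ls=":",
                label="baseline (run 0)")
    ax.axhline(threshold, color="r", ls="--", lw=1, label=f"threshold {threshold:g}")
    ax.set_xlabel("minute")
    ax.set_ylabel("sBP (mmHg)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_metric_bars(summaries: dict, metric: str, path=None):
    """Bar chart with SD error bars: one bar per labelled report summary.

    ``summaries`` maps label -> report payload (as read from report JSON).
    """
    labels = list(summaries)
    means = [summaries[k]["mean"][metric] for k in labels]
    sds = [summaries[k]["sd"][metric] for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.bar(labels, means, yerr=sds, capsize=4, color="steelblue")
    ax.set_ylabel(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
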