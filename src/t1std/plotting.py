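"""Progression and cohort plots (matplotlib, non-interactive backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def progression_plot(results, out_path, title="Standardisation progression"):
    """Per-map progression from original to standardised mean T1 with the
    cumulative impact of each bias component in between."""
    fig, ax = plt.subplots(figsize=(8, 5))
    n_comp = max(len(r.bias_components) for r in results)
    xs = np.arange(n_comp + 1)
    for r in results:
        means = [r.mean_before]
        current = r.values_original.astype(float).copy()
        for _, comp in r.bias_components:
            current = current - comp
            means.append(float(current.mean()))
        ax.plot(xs[: len(means)], means, marker="o", alpha=0.6, lw=1)
    labels = ["original"] + [name for name, _ in results[0].bias_components]
    ax.set_xticks(xs[: len(labels)], labels, rotation=30)
    ax.set_ylabel("mean T1 (ms)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def cohort_boxplot(groups_before: dict, groups_after: dict, out_path):
    """Side-by-side per-cohort boxplots of mean T1 before/after
    standardisation."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, groups, label in (
        (axes[0], groups_before, "before"),
        (axes[1], groups_after, "after"),
    ):
        ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
        ax.set_title(f"{label} standardisation")
    axes[0].set_ylabel("mean T1 (ms)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
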