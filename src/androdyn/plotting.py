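"""Diagnostic figures: per-cluster membership-colored traces, the objective
elbow curve, and composition strip charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_cluster_traces(profiles, results, assignment, path=None):
    """Per-cluster temporal traces colored by membership value."""
    frame = profiles.profiles if hasattr(profiles, "profiles") else profiles
    times = np.asarray(frame.columns, dtype=float)
    mapping = getattr(assignment, "labels", assignment)
    clusters = sorted(mapping.unique())
    ncol = min(len(clusters), 3)
    nrow = int(np.ceil(len(clusters) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharey=True)
    maxm = assignment.max_membership
    cmap = plt.get_cmap("viridis")
    for ax, cluster in zip(axes.flat, clusters):
        members = mapping.index[mapping == cluster]
        for pid in members:
            ax.plot(times, frame.loc[pid], lw=0.5, alpha=0.6,
                    color=cmap(float(maxm[pid])))
        ax.set_title(f"cluster {cluster} (n={len(members)})")
        ax.set_xlabel("time (min)")
    for ax in axes.flat[len(clusters):]:
        ax.axis("off")
    axes[0][0].set_ylabel("standardized log2 ratio")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_objective_curve(diagnostics: pd.DataFrame, k_star: int | None = None,
                         path=None):
    """J(k) elbow curve with the selected k marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(diagnostics.index, diagnostics["J"], marker="o")
    if k_star is not None:
        ax.axvline(k_star, color="crimson", ls="--", lw=1,
                   label=f"elbow k={k_star}")
        ax.legend()
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("FCM objective J")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_composition_strip(pct: pd.DataFrame, path=None):
    """Strip chart of per-cluster category percentages."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, category in enumerate(pct.columns):
        ax.scatter([i] * len(pct), pct[category], s=30)
        for cluster, v in pct[category].items():
            ax.annotate(str(cluster), (i, v), fontsize=7,
                        textcoords="offset points", xytext=(4, 0))
    ax.set_xticks(range(len(pct.columns)))
    ax.set_xticklabels(pct.columns, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("% of cluster")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
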