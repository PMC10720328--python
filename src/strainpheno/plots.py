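"""Presentation figures (SVG). Smoke-tested only; numbers live in the CSVs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def bic_curve_plot(curve: pd.DataFrame, chosen_k: int, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["k"], curve["bic"], "o-")
    ax.axvline(chosen_k, color="crimson", ls="--", lw=1)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("BIC")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def centroid_plot(centroids: dict, path: str | Path) -> Path:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for lab, c in sorted(centroids.items()):
        axes[0].plot(c.time, np.abs(c.strain), label=f"cluster {lab} (n={c.n})")
        axes[1].plot(c.time[:-1], c.strain_rate, label=f"cluster {lab}")
    axes[0].set_xlabel("time (s)")
    axes[0].set_ylabel("strain magnitude (%)")
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylabel("strain rate (%/s)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def radar_chart(profile: pd.DataFrame, path: str | Path) -> Path:
    labels = list(profile.columns)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(figsize=(4.5, 4.5), subplot_kw=dict(polar=True))
    for name, row in profile.iterrows():
        vals = row.to_numpy()
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=name)
        ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.08)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7, loc="lower right", bbox_to_anchor=(1.15, -0.1))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def shap_summary(report, path: str | Path) -> Path:
    """Beeswarm-style strip plot of Shapley contributions per cluster."""
    k = report.values.shape[1]
    d = report.values.shape[2]
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    rng = np.random.default_rng(0)
    for c in range(k):
        ax = axes[c]
        for j in range(d):
            vals = report.values[:, c, j]
            ax.scatter(
                vals, j + rng.uniform(-0.18, 0.18, vals.size), s=4, alpha=0.5
            )
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_title(f"cluster {c + 1}", fontsize=9)
        ax.set_xlabel("contribution to posterior")
    axes[0].set_yticks(range(d))
    axes[0].set_yticklabels(report.feature_names, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def km_plot(km_by_cluster: dict, path: str | Path, outcome: str = "cv") -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for lab, df in sorted(km_by_cluster.items()):
        ax.step(df["time"], 100 * df["cumulative_incidence"], where="post",
                label=f"cluster {lab}")
    ax.set_xlabel("follow-up (years)")
    ax.set_ylabel(f"cumulative incidence of {outcome} events (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
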