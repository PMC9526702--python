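"""Plot artifacts: stacked composition bars, volcano, PCA, clustered heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .niches import NICHES

_NICHE_COLORS = {
    "LE": "#4daf4a",
    "IT": "#377eb8",
    "CT": "#984ea3",
    "MVP": "#e41a1c",
    "PAN": "#ff7f00",
}


def stacked_bar_composition(table: pd.DataFrame, path: str | Path) -> None:
    """Stacked bars of per-sample niche vote probabilities (long-format input)."""
    wide = table.pivot(index="sample", columns="niche", values="probability")
    wide = wide[[n for n in NICHES]]
    fig, ax = plt.subplots(figsize=(max(6, 0.12 * len(wide)), 4))
    bottom = np.zeros(len(wide))
    for niche in NICHES:
        ax.bar(range(len(wide)), wide[niche], bottom=bottom,
               color=_NICHE_COLORS[niche], label=niche, width=1.0)
        bottom += wide[niche].to_numpy()
    ax.set_xlim(-0.5, len(wide) - 0.5)
    ax.set_ylabel("niche vote probability")
    ax.set_xticks([])
    ax.legend(ncol=5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def volcano_plot(result, path: str | Path) -> None:
    """Difference vs -log10 p scatter; significant proteins highlighted."""
    t = result.table
    fig, ax = plt.subplots(figsize=(5, 4))
    neg_log_p = -np.log10(np.clip(t["p_value"], 1e-300, None))
    ax.scatter(t["diff"], neg_log_p, s=4, c="grey", alpha=0.5)
    sig = t["significant"]
    ax.scatter(t.loc[sig, "diff"], neg_log_p[sig], s=6, c="#e41a1c")
    ax.set_xlabel("difference")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{int(sig.sum())} significant (FDR {result.params.fdr}, s0 {result.params.s0})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_plot(scores: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = labels.loc[scores.index]
    for g in pd.unique(labels):
        sel = labels == g
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"], s=12, label=str(g))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def clustered_heatmap(
    matrix_values: pd.DataFrame,
    clustering,
    annotations: pd.DataFrame | None,
    path: str | Path,
    max_proteins: int = 500,
) -> None:
    """Heatmap with samples in dendrogram leaf order; top-variance proteins shown."""
    order = clustering.leaf_order
    vals = matrix_values[order]
    if len(vals) > max_proteins:
        keep = vals.var(axis=1).nlargest(max_proteins).index
        vals = vals.loc[keep]
    n_tracks = 0 if annotations is None else annotations.shape[1]
    fig, axes = plt.subplots(
        2 + n_tracks,
        1,
        figsize=(8, 6),
        gridspec_kw={"height_ratios": [1] + [0.15] * n_tracks + [5]},
    )
    axes = np.atleast_1d(axes)
    hierarchy.dendrogram(clustering.linkage, ax=axes[0], no_labels=True, color_threshold=0)
    axes[0].set_yticks([])
    if annotations is not None:
        ann = annotations.loc[order]
        for k, col in enumerate(ann.columns):
            codes = pd.Categorical(ann[col]).codes[None, :]
            axes[1 + k].imshow(codes, aspect="auto", cmap="tab10")
            axes[1 + k].set_yticks([0])
            axes[1 + k].set_yticklabels([col], fontsize=7)
            axes[1 + k].set_xticks([])
    axes[-1].imshow(vals.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    axes[-1].set_xticks([])
    axes[-1].set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
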