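"""Static figures for the report: histograms, density overlays, topologies."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .compare import DensityCurve, ThresholdComparison
from .mapper import MapperGraph
from .profile import MissingnessProfile

__all__ = [
    "plot_missingness_histograms",
    "plot_density_overlay",
    "plot_mapper_graphs",
]


def plot_missingness_histograms(profile: MissingnessProfile, path: str | Path) -> Path:
    """Two-panel histogram: missing counts per protein (top) and per sample."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6))
    w1 = np.diff(profile.protein_hist_edges)
    ax1.bar(profile.protein_hist_edges[:-1], profile.protein_hist_counts,
            width=w1, align="edge", color="#3b6fb6", edgecolor="white")
    ax1.set_xlabel("missing values per protein")
    ax1.set_ylabel("proteins")
    w2 = np.diff(profile.sample_hist_edges)
    ax2.bar(profile.sample_hist_edges[:-1], profile.sample_hist_counts,
            width=w2, align="edge", color="#c0392b", edgecolor="white")
    ax2.set_xlabel("missing values per sample")
    ax2.set_ylabel("samples")
    fig.suptitle(f"overall missing fraction {profile.overall_fraction:.4f}; "
                 f"{profile.n_complete_proteins} complete proteins")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_density_overlay(
    d_non_imputed: DensityCurve,
    d_imputed: DensityCurve,
    comparison: ThresholdComparison | None,
    path: str | Path,
    title: str = "",
) -> Path:
    """Overlayed densities (non-imputed blue, imputed red) with dashed peak lines."""
    fig, ax = plt.subplots(figsize=(7, 4.2))
    ax.plot(d_non_imputed.grid, d_non_imputed.density, color="#3b6fb6", label="non-imputed")
    ax.fill_between(d_non_imputed.grid, d_non_imputed.density, alpha=0.2, color="#3b6fb6")
    ax.plot(d_imputed.grid, d_imputed.density, color="#c0392b", label="imputed")
    ax.fill_between(d_imputed.grid, d_imputed.density, alpha=0.2, color="#c0392b")
    if comparison is not None:
        ax.axvline(comparison.peak_non_imputed, ls="--", color="#3b6fb6")
        ax.axvline(comparison.peak_imputed, ls="--", color="#c0392b")
        title = title or (
            f"τ={comparison.threshold:.2f}  kept={comparison.n_proteins_kept}  "
            f"KS D={comparison.ks_D:.3f} p={comparison.ks_p:.3g}  "
            f"Δpeak={comparison.peak_distance:.3f}"
        )
    ax.set_xlabel("mean log2 intensity per sample")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_mapper_graphs(
    graphs: list[tuple[str, MapperGraph]],
    path: str | Path,
    color_by: str = "enrichment",
    seed: int = 0,
) -> Path:
    """Side-by-side force-directed renderings of one or more Mapper graphs.

    Node colour encodes mean missingness percentage (``enrichment``) or
    community label; node size scales with membership.  The layout is
    seeded and purely cosmetic.
    """
    fig, axes = plt.subplots(1, len(graphs), figsize=(6 * len(graphs), 5.5), squeeze=False)
    for ax, (label, g) in zip(axes[0], graphs):
        nxg = g.to_networkx()
        pos = nx.spring_layout(nxg, seed=seed)
        sizes = [40 + 18 * nxg.nodes[n]["size"] for n in nxg.nodes]
        if color_by == "community" and g.communities:
            colors = [g.communities.get(n, 0) for n in nxg.nodes]
            cmap, label_cb = "tab20", "community"
        else:
            colors = [g.node_enrichment.get(n, 0.0) for n in nxg.nodes]
            cmap, label_cb = "viridis", "mean missingness %"
        nx.draw_networkx_edges(nxg, pos, ax=ax, alpha=0.4)
        coll = nx.draw_networkx_nodes(
            nxg, pos, ax=ax, node_size=sizes, node_color=colors, cmap=cmap
        )
        if label_cb == "mean missingness %":
            fig.colorbar(coll, ax=ax, label=label_cb, shrink=0.8)
        s = g.summary()
        ax.set_title(f"{label}\nnodes={s['n_nodes']} edges={s['n_edges']} "
                     f"components={s['n_connected_components']}")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
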