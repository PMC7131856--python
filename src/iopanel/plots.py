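"""Static figure rendering: volcano, clustered heatmap, Venn, PCA, boxplots.

Figures are publication-style analogues of a targeted-panel study's
standard panels. Heatmap rows are hierarchically clustered with average
linkage on Euclidean distance of row-z-scored log2 nRPM. Venn diagrams
are drawn directly with matplotlib circle patches (2 or 3 sets).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Circle
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def volcano(table: pd.DataFrame, ax=None, title: str = ""):
    """log2 fold change vs -log10 p, DEGs colored by direction."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(table["p"])
    colors = table["direction"].map(
        {"up": "#d62728", "down": "#1f77b4", "none": "#bbbbbb"}
    )
    ax.scatter(table["log2_fc"], neglogp, s=8, c=colors, linewidths=0)
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="k")
    for x in (-1, 1):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    return ax


def clustered_heatmap(logx: pd.DataFrame, genes, ax=None, title: str = ""):
    """Row-clustered heatmap of z-scored log2 nRPM for a gene subset."""
    sub = logx.loc[[g for g in genes if g in logx.index]]
    if sub.empty:
        raise ValueError("no genes to draw")
    z = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    if len(z) > 2:
        link = hierarchy.linkage(pdist(z.to_numpy()), method="average")
        order = hierarchy.leaves_list(link)
        z = z.iloc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(z))))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_yticks(range(len(z)))
    ax.set_yticklabels(z.index, fontsize=5)
    ax.set_xticks(range(z.shape[1]))
    ax.set_xticklabels(z.columns, fontsize=5, rotation=90)
    ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.6, label="z(log2 nRPM)")
    return ax


_VENN2_POS = [(-0.5, 0.0), (0.5, 0.0)]
_VENN3_POS = [(-0.5, -0.29), (0.5, -0.29), (0.0, 0.58)]


def venn(sizes: dict[str, int], labels: list[str], ax=None, title: str = ""):
    """2- or 3-circle Venn with region counts from an overlap partition.

    ``sizes`` maps '&'-joined label combinations to region cardinalities,
    as produced by ``OverlapResult.sizes()``.
    """
    if len(labels) not in (2, 3):
        raise ValueError("venn supports 2 or 3 sets")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = _VENN2_POS if len(labels) == 2 else _VENN3_POS
    colors = ["#1f77b4", "#2ca02c", "#9467bd"]
    for (x, y), lab, c in zip(pos, labels, colors):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3, color=c))
        ax.annotate(lab, (x, y + 1.05), ha="center", fontsize=9)
    centers = dict(zip(labels, pos))
    for combo, n in sizes.items():
        members = combo.split("&")
        xs = [centers[m][0] for m in members]
        ys = [centers[m][1] for m in members]
        # pull exclusive regions outward, shared regions to the centroid
        shrink = 1.0 if len(members) > 1 else 1.35
        ax.annotate(
            str(n),
            (np.mean(xs) * shrink, np.mean(ys) * shrink),
            ha="center", va="center", fontsize=10,
        )
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    return ax


def pca_scatter(coords: pd.DataFrame, groups: pd.Series, var_frac, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    for i, (g, sub) in enumerate(coords.groupby(groups)):
        ax.scatter(sub["PC1"], sub["PC2"], s=25, label=str(g))
    ax.set_xlabel(f"PC1 ({100 * var_frac[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * var_frac[1]:.1f}%)")
    ax.legend(fontsize=8)
    return ax


def gene_boxplots(nrpm: pd.DataFrame, genes, groups: pd.Series, ax=None):
    """Per-gene nRPM boxplots split by sample group."""
    genes = [g for g in genes if g in nrpm.index]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.8 * len(genes)), 4))
    levels = list(pd.unique(groups))
    width = 0.8 / len(levels)
    for i, lvl in enumerate(levels):
        cols = groups.index[groups == lvl]
        data = [nrpm.loc[g, cols].to_numpy() for g in genes]
        positions = np.arange(len(genes)) + (i - (len(levels) - 1) / 2) * width
        ax.boxplot(data, positions=positions, widths=width * 0.9)
    ax.set_xticks(range(len(genes)))
    ax.set_xticklabels(genes, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("nRPM")
    return ax


def render_figures(
    outdir: Path,
    report: dict,
    logx: pd.DataFrame,
    deg_tables: dict[str, pd.DataFrame],
) -> list[Path]:
    """Write the standard figure set for a finished run; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in deg_tables.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        volcano(table, ax=ax, title=name)
        p = outdir / f"volcano_{name}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

        degs = table.index[table["is_deg"]].tolist()
        if degs:
            fig, ax = plt.subplots()
            clustered_heatmap(logx, degs, ax=ax, title=name)
            p = outdir / f"heatmap_{name}.png"
            fig.savefig(p, dpi=110, bbox_inches="tight")
            plt.close(fig)
            written.append(p)

    for key, sizes in report.get("overlaps", {}).items():
        if not isinstance(sizes, dict):
            continue
        labels = sorted({lab for combo in sizes for lab in combo.split("&")})
        if len(labels) not in (2, 3):
            continue
        fig, ax = plt.subplots(figsize=(4, 4))
        venn(sizes, labels, ax=ax, title=key)
        p = outdir / f"venn_{key}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
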