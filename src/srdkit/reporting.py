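"""Presentation artifacts: annotated pair tables, SRD heatmaps, category plots.

Figures never stand alone: each plot writes a delimited sidecar table with the
exact numbers rendered, and plotting never mutates or reorders the analysis
outputs it is given.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # deterministic, headless rendering

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colors as mcolors
from matplotlib.patches import Rectangle

from .stats import categorize_small_srd

__all__ = [
    "ANNOTATED_COLUMNS",
    "serialize_srd",
    "write_annotated_table",
    "read_annotated_table",
    "srd_heatmap",
    "category_frequency_plot",
]

ANNOTATED_COLUMNS = [
    "best_snp",
    "gene_symbol",
    "kegg_gene_id",
    "metabolite_name",
    "kegg_metabolite_id",
    "min_p",
    "category",
    "srd",
    "mapping_source",
    "proxy",
]

_CATEGORY_ORDER = {"R": 0, "S_plus": 1, "S_minus": 2, "NS": 3}

# colorblind-safe reserved encodings for the non-numeric outcomes
_INF_COLOR = "#b0b0b0"
_NA_COLOR = "#ffffff"


def serialize_srd(value: float) -> str:
    """Serialize an SRD float to the report convention: integer, Inf or NA."""
    if np.isnan(value):
        return "NA"
    if np.isinf(value):
        return "Inf"
    return str(int(value))


def write_annotated_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write the annotated pair table, tab-delimited, deterministic order.

    Rows sort by category (R, S+, S-, NS) then ascending min p.  SRD values
    serialize as integer / ``Inf`` / ``NA``; proxy-substituted metabolites
    carry a ``*`` marker appended to their name.  Missing optional columns
    are emitted empty so the column order is always the full fixed set.
    """
    df = pairs.copy()
    for col in ANNOTATED_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "proxy" else False
    df["_cat"] = df["category"].astype(str).map(_CATEGORY_ORDER).fillna(9)
    df = df.sort_values(["_cat", "min_p"], kind="mergesort").drop(columns="_cat")
    out = df[ANNOTATED_COLUMNS].copy()
    out["srd"] = df["srd"].astype(float).map(serialize_srd)
    proxy = df["proxy"].astype(bool)
    out["metabolite_name"] = np.where(
        proxy, df["metabolite_name"].astype(str) + "*", df["metabolite_name"].astype(str)
    )
    out["proxy"] = np.where(proxy, "yes", "no")
    out.to_csv(path, sep="\t", index=False)


def read_annotated_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_annotated_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"srd": str})

    def _parse(s) -> float:
        if pd.isna(s) or s == "NA":
            return np.nan
        return np.inf if s == "Inf" else float(s)

    df["srd"] = df["srd"].map(_parse)
    df["proxy"] = df["proxy"].eq("yes")
    return df


def _pair_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Gene x metabolite SRD matrix (alphabetical axes, NaN where untested)."""
    return pairs.pivot_table(
        index="kegg_gene_id",
        columns="kegg_metabolite_id",
        values="srd",
        aggfunc="min",
        dropna=False,
    ).sort_index(axis=0).sort_index(axis=1)


def srd_heatmap(
    pairs: pd.DataFrame,
    path: str | Path,
    highlight: set[tuple[str, str]] | None = None,
    dpi: int = 150,
) -> pd.DataFrame:
    """Gene x metabolite heatmap of SRD values with highlighted pair boxes.

    Cell color encodes the finite SRD on a sequential ramp; disconnected
    (``Inf``) cells use a reserved gray and absent (``NA``) cells white, both
    outside the numeric ramp.  Pairs in ``highlight`` are outlined.  Axis
    order is alphabetical, so regeneration from the same inputs is
    deterministic.  Returns the plotted matrix, which is also written next to
    the image as ``<path>.tsv``.
    """
    if pairs.empty or not np.isfinite(pairs["srd"].astype(float)).any():
        raise ValueError("srd_heatmap: need at least one finite SRD value")
    mat = _pair_matrix(pairs)
    data = mat.to_numpy(dtype=float)
    finite = data[np.isfinite(data)]
    vmax = max(float(finite.max()), 1.0)

    cmap = plt.get_cmap("viridis").copy()
    masked = np.ma.masked_invalid(np.where(np.isinf(data), np.nan, data))

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * mat.shape[1] + 2), max(3.0, 0.5 * mat.shape[0] + 2))
    )
    ax.set_facecolor(_NA_COLOR)
    # paint Inf cells first, then the numeric layer on top
    inf_layer = np.where(np.isinf(data), 1.0, np.nan)
    ax.pcolormesh(
        np.ma.masked_invalid(inf_layer),
        cmap=mcolors.ListedColormap([_INF_COLOR]),
        vmin=0,
        vmax=1,
    )
    mesh = ax.pcolormesh(masked, cmap=cmap, vmin=0, vmax=vmax)
    fig.colorbar(mesh, ax=ax, label="SRD (reaction steps)")
    ax.set_xticks(np.arange(mat.shape[1]) + 0.5, mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(mat.shape[0]) + 0.5, mat.index, fontsize=7)
    ax.set_xlabel("metabolite (KEGG ID)")
    ax.set_ylabel("gene (KEGG ID)")
    for gene, met in sorted(highlight or ()):
        if gene in mat.index and met in mat.columns:
            i = mat.index.get_loc(gene)
            j = mat.columns.get_loc(met)
            ax.add_patch(Rectangle((j, i), 1, 1, fill=False, edgecolor="black", lw=2))
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    mat.to_csv(Path(str(path) + ".tsv"), sep="\t")
    return mat


def category_frequency_plot(
    pairs: pd.DataFrame,
    path: str | Path,
    threshold: int = 8,
    dpi: int = 150,
) -> pd.DataFrame:
    """Per-category frequencies of small (<= threshold) vs large SRD.

    Bars show the percentage of finite-SRD pairs at or below the threshold
    per significance category, annotated with the finite-pair count n; the
    infinite/NA tallies appear in the sidecar table ``<path>.tsv``.  Empty
    categories render with n=0.
    """
    table = categorize_small_srd(pairs, threshold=threshold)
    cats = table["category"].astype(str).tolist()
    x = np.arange(len(cats))
    small = table["pct_small"].fillna(0.0).to_numpy()
    large = table["pct_large"].fillna(0.0).to_numpy()

    fig, ax = plt.subplots(figsize=(1.5 * max(len(cats), 2) + 2, 4))
    width = 0.38
    ax.bar(x - width / 2, small, width, label=f"SRD <= {threshold}", color="#888888")
    ax.bar(x + width / 2, large, width, label=f"SRD > {threshold}", color="#333333")
    for xi, n in zip(x, table["n_finite"]):
        ax.text(xi, 101, f"n={n}", ha="center", fontsize=8)
    ax.set_xticks(x, cats)
    ax.set_ylim(0, 112)
    ax.set_ylabel("% of finite-SRD pairs")
    ax.set_xlabel("significance category")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    table.to_csv(Path(str(path) + ".tsv"), sep="\t", index=False)
    return table
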