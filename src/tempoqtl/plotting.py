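"""Plot helpers: heritability curves, cluster profiles, temporal Manhattan
and allele-trajectory panels.  Every function draws on a provided or fresh
matplotlib Axes and returns it."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "plot_heritability",
    "plot_cluster_profiles",
    "plot_temporal_manhattan",
    "plot_allele_trajectory",
]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_heritability(h2: pd.DataFrame, ax=None):
    """H2 over DAP, one line per trait (columns: trait, DAP, H2)."""
    ax = _axes(ax)
    for trait, grp in h2.groupby("trait"):
        grp = grp.sort_values("DAP")
        ax.plot(grp["DAP"], grp["H2"], label=trait)
    ax.set_xlabel("DAP")
    ax.set_ylabel("broad-sense heritability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_cluster_profiles(result, ax=None):
    """Mean temporal profile per cluster from a ClusterResult."""
    ax = _axes(ax)
    for cluster, row in result.mean_profiles.iterrows():
        ax.plot(row.index, row.values, label=f"cluster {cluster}")
    ax.set_xlabel("DAP")
    ax.set_ylabel("trait value")
    ax.legend(fontsize="small")
    return ax


def plot_temporal_manhattan(hits: pd.DataFrame, marker_meta: pd.DataFrame, ax=None):
    """DAP (y) against genome position (x) for high-confidence hits.

    `hits` columns: marker, trait, DAP, tier; `marker_meta` columns:
    id, chrom, pos.  Stringent hits are drawn solid, lower-tier open.
    """
    ax = _axes(ax)
    meta = marker_meta.set_index("id")
    chroms = list(dict.fromkeys(marker_meta["chrom"]))
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += int(marker_meta.loc[marker_meta["chrom"] == c, "pos"].max()) + 1
    if not hits.empty:
        x = hits["marker"].map(
            lambda m: offsets[meta.loc[m, "chrom"]] + meta.loc[m, "pos"]
        )
        stringent = hits["tier"] == "stringent"
        ax.scatter(x[stringent], hits.loc[stringent, "DAP"], s=12, marker="s",
                   label="stringent")
        ax.scatter(x[~stringent], hits.loc[~stringent, "DAP"], s=12, marker="o",
                   facecolors="none", edgecolors="C1", label="lower")
    for c in chroms[1:]:
        ax.axvline(offsets[c], color="grey", lw=0.5)
    ax.set_xlabel("genome position")
    ax.set_ylabel("DAP")
    if not hits.empty:
        ax.legend(fontsize="small")
    return ax


def plot_allele_trajectory(series, ax=None):
    """Per-allele phenotype means over DAP from an AlleleEffectSeries.

    Days where the marker was a GWAS hit are starred: filled for the
    stringent tier, open for the lower tier.
    """
    ax = _axes(ax)
    t = series.table
    ax.plot(t["DAP"], t["mean0"], label=series.alleles[0])
    ax.plot(t["DAP"], t["mean2"], label=series.alleles[1])
    top = np.nanmax(np.column_stack([t["mean0"], t["mean2"]]), axis=1)
    for tier, mk in (("stringent", "*"), ("lower", "+")):
        sel = t["hit_tier"] == tier
        ax.plot(t.loc[sel, "DAP"], top[sel] * 1.05, mk, color="k", ls="none")
    ax.set_xlabel("DAP")
    ax.set_ylabel(series.trait)
    ax.legend(fontsize="small")
    return ax
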