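"""Temporal trait profiles: daily percentile ranks, hierarchical clustering
of accession profiles, ideotype classification, and top/bottom ranking.

Percentile convention: 100 * (rank - 1) / (n - 1) with average ranks for
ties, so each day's column spans [0, 100] and is invariant to any strictly
monotone transform of the underlying values.

Clustering follows the study's recipe: Euclidean distances between complete
temporal profiles (default DAP 12-56) with Ward agglomeration, tree cut at k
clusters.  The "PCA-weighted mean" coordinate used by clustergram displays is
defined here as the rank-weighted average of member scores on the first
principal component of the profile matrix.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "percentile_rank",
    "percentile_table",
    "select_ideotypes",
    "cluster_profiles",
    "rank_top_bottom",
    "ClusterResult",
    "IdeotypeReport",
    "EARLY_WINDOW",
    "LATE_WINDOW",
]

# cold phase (15 C) and warm phase (32 C) evaluation windows
EARLY_WINDOW = (15, 31)
LATE_WINDOW = (39, 56)


def percentile_rank(values: np.ndarray) -> np.ndarray:
    """Percentiles in [0, 100]: 100*(rank-1)/(n-1), average ranks for ties.

    Missing values stay missing.  With all values equal every percentile is
    50 (tie policy).
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = 100.0 * (ranks - 1.0) / (n - 1.0)
    return out


def percentile_table(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (per-DAP) percentile ranks of an accession x DAP table."""
    out = {}
    for col in values.columns:
        out[col] = percentile_rank(values[col].to_numpy())
    return pd.DataFrame(out, index=values.index)


@dataclasses.dataclass
class IdeotypeReport:
    window: tuple[int, int]
    positives: list[str]
    negatives: list[str]
    mean_percentiles: pd.DataFrame  # accession x (wue, height_to_biomass)

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "positives": self.positives,
            "negatives": self.negatives,
            "mean_percentiles": {
                acc: {
                    "wue": float(row["wue"]),
                    "height_to_biomass": float(row["height_to_biomass"]),
                }
                for acc, row in self.mean_percentiles.iterrows()
            },
        }


def select_ideotypes(
    wue_percentiles: pd.DataFrame,
    ratio_percentiles: pd.DataFrame,
    window: tuple[int, int],
    wue_top: float = 90.0,
    ratio_bottom: float = 5.0,
) -> IdeotypeReport:
    """Classify ideotype-positive / -negative accessions over a DAP window.

    Positive: mean WUE percentile >= `wue_top` (top 10%) and mean
    height-to-biomass-ratio percentile <= `ratio_bottom` (bottom 5%).
    Negative mirrors it: WUE <= 100-wue_top and ratio >= 100-ratio_bottom.
    Percentile tables are accession x DAP.
    """
    lo, hi = window
    cols = [c for c in wue_percentiles.columns if lo <= c <= hi]
    if not cols:
        raise ValueError("empty ideotype window")
    common = wue_percentiles.index.intersection(ratio_percentiles.index)
    wue_mean = wue_percentiles.loc[common, cols].mean(axis=1)
    ratio_mean = ratio_percentiles.loc[common, cols].mean(axis=1)
    positives = sorted(common[(wue_mean >= wue_top) & (ratio_mean <= ratio_bottom)])
    negatives = sorted(
        common[(wue_mean <= 100.0 - wue_top) & (ratio_mean >= 100.0 - ratio_bottom)]
    )
    means = pd.DataFrame(
        {"wue": wue_mean, "height_to_biomass": ratio_mean}, index=common
    )
    return IdeotypeReport((lo, hi), list(positives), list(negatives), means)


@dataclasses.dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # accession -> cluster id (1..k)
    mean_profiles: pd.DataFrame  # cluster x DAP
    linkage: np.ndarray
    pca_weighted_means: pd.Series  # cluster -> clustergram coordinate
    dropped: list[str]  # accessions with incomplete profiles


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int,
    dap_range: tuple[int, int] = (12, 56),
) -> ClusterResult:
    """Ward hierarchical clustering of temporal trait profiles.

    `profiles` is accession x DAP.  Accessions with any gap inside
    `dap_range` are dropped with a warning.  The tree is cut at k clusters;
    cluster ids are relabelled 1..k by ascending mean profile level so the
    labelling is input-order invariant (rows are sorted by accession id
    before linkage).
    """
    lo, hi = dap_range
    cols = [c for c in profiles.columns if lo <= c <= hi]
    sub = profiles[cols].sort_index()
    complete = sub.dropna()
    dropped = sorted(set(sub.index) - set(complete.index))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} accessions with incomplete profiles")
    if k > len(complete):
        raise ValueError("more clusters requested than accessions")
    X = complete.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters by ascending overall mean so ids are deterministic
    order = (
        pd.Series(X.mean(axis=1), index=raw).groupby(level=0).mean().sort_values()
    )
    relabel = {old: new for new, old in enumerate(order.index, start=1)}
    labels = np.array([relabel[c] for c in raw])
    assignments = pd.Series(labels, index=complete.index, name="cluster")
    mean_profiles = (
        complete.groupby(assignments).mean().rename_axis("cluster")
    )
    # clustergram coordinate: rank-weighted mean of member PC1 scores
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    if Vt[0, np.argmax(np.abs(Vt[0]))] < 0:
        pc1 = -pc1
    coords = {}
    for c in range(1, k + 1):
        member_scores = pc1[labels == c]
        ranks = stats.rankdata(member_scores, method="average")
        coords[c] = float(np.average(member_scores, weights=ranks))
    return ClusterResult(
        k=k,
        assignments=assignments,
        mean_profiles=mean_profiles,
        linkage=Z,
        pca_weighted_means=pd.Series(coords, name="pca_weighted_mean"),
        dropped=dropped,
    )


def rank_top_bottom(
    values: pd.Series, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Top and bottom ceil(fraction*n) accessions by value at one DAP.

    Ties at the cut are broken by accession id (ascending) for determinism.
    """
    s = values.dropna()
    n = len(s)
    count = int(np.ceil(fraction * n))
    # stable secondary ordering by accession id
    df = s.rename("v").reset_index()
    df.columns = ["accession", "v"]
    top = df.sort_values(["v", "accession"], ascending=[False, True])[
        "accession"
    ].head(count)
    bottom = df.sort_values(["v", "accession"], ascending=[True, True])[
        "accession"
    ].head(count)
    return sorted(top), sorted(bottom)
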