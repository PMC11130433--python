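"""Longitudinal GWAS and transient-QTL track assembly.

Runs the stepwise mixed-model association once per trait per day, collects
the high-confidence markers (union of the multiple-Bonferroni and extended
BIC models, tiered stringent/lower), and assembles them into time-resolved
tracks: maximal consecutive-DAP runs per marker and trait.  A track is
"transient" when a nonsignificant day separates two runs or the track ends
before the last day — the signature of QTL that switch on/off with
developmental stage or temperature.  Also detects pleiotropic markers
(significant for two or more traits) and computes per-allele phenotype
trajectories with Welch tests per day.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mlmm import MixedLMM, MLMMResults, kinship_eigendecomposition
from .statgen import (
    GenotypeMatrix,
    astle_balding_kinship,
    boxcox_transform,
    genotype_pca,
    maf_filter_impute,
)

__all__ = [
    "GwasConfig",
    "longitudinal_gwas",
    "hits_table",
    "detect_transient",
    "detect_pleiotropy",
    "allele_effect_series",
    "TransientTrack",
    "AlleleEffectSeries",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GwasConfig:
    n_pcs: int = 3
    maf_min: float = 0.05
    alpha: float = 0.05
    gamma: float = 1.0
    max_steps: int = 20
    pseudo_h2_stop: float = 0.01
    # Box-Cox applied when a normality test rejects at this level (None = never)
    boxcox_alpha: float | None = 0.01


def _maybe_boxcox(y: np.ndarray, alpha: float | None) -> tuple[np.ndarray, float | None]:
    if alpha is None:
        return y, None
    if len(y) < 8 or np.ptp(y) == 0:
        return y, None
    stat, p = stats.normaltest(y)
    if p >= alpha:
        return y, None
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 1e-6 * max(np.ptp(y), 1.0)
    lam, yt = boxcox_transform(y + shift)
    return yt, lam


def longitudinal_gwas(
    geno: GenotypeMatrix,
    traits_table: pd.DataFrame,
    trait: str,
    daps: Sequence[int] | None = None,
    config: GwasConfig | None = None,
) -> dict[int, MLMMResults]:
    """One MLMM fit per DAP for a single trait.

    `traits_table` is long format (accession, trait, DAP, value).  Marker
    filtering, kinship and PCs are computed once on the full accession set;
    per DAP, accessions with missing phenotype are dropped case-wise (the
    kinship eigendecomposition is reused whenever the case set is complete).
    Failed single-day fits are logged and skipped, never fatal.
    """
    cfg = config or GwasConfig()
    sub = traits_table[traits_table["trait"] == trait]
    wide = sub.pivot_table(index="accession", columns="DAP", values="value")
    common = [a for a in geno.accessions if a in wide.index]
    if len(common) < 10:
        raise ValueError("too few accessions shared between genotypes and traits")
    geno_c = geno.subset_accessions(common)
    filtered = maf_filter_impute(geno_c, cfg.maf_min)
    K = astle_balding_kinship(filtered)
    pcs = genotype_pca(filtered, cfg.n_pcs).to_numpy()
    full_eig = kinship_eigendecomposition(K)
    wide = wide.loc[common]
    if daps is None:
        daps = sorted(int(c) for c in wide.columns)
    meta = filtered.markers[["id", "chrom", "pos"]]
    fits: dict[int, MLMMResults] = {}
    for dap in daps:
        if dap not in wide.columns:
            continue
        y_all = wide[dap].to_numpy(dtype=float)
        ok = np.isfinite(y_all)
        try:
            idx = np.nonzero(ok)[0]
            y = y_all[idx]
            if np.ptp(y) == 0:
                raise ValueError("constant phenotype")
            y, _lam = _maybe_boxcox(y, cfg.boxcox_alpha)
            X = np.column_stack([np.ones(len(idx)), pcs[idx]])
            if ok.all():
                k_eig = full_eig
            else:
                k_eig = kinship_eigendecomposition(K.values[np.ix_(idx, idx)])
            model = MixedLMM(
                y, X, None, filtered.dosages[idx], meta, k_eig=k_eig
            )
            fits[dap] = model.fit(
                max_steps=cfg.max_steps,
                pseudo_h2_stop=cfg.pseudo_h2_stop,
                alpha=cfg.alpha,
                gamma=cfg.gamma,
                m_effective=filtered.n_markers,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("GWAS fit failed for %s at DAP %s: %s", trait, dap, exc)
    return fits


def hits_table(fits_by_trait: dict[str, dict[int, MLMMResults]]) -> pd.DataFrame:
    """Long hit tensor (marker, trait, DAP, tier, p) over all fits."""
    frames = []
    for trait, fits in fits_by_trait.items():
        for dap, res in fits.items():
            frame = res.hits_frame(trait=trait, dap=dap)
            if not frame.empty:
                frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["marker", "trait", "DAP", "tier", "p"])
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass
class TransientTrack:
    marker: str
    trait: str
    significant_daps: dict[int, str]  # DAP -> tier
    runs: list[tuple[int, int]]
    transient: bool

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "trait": self.trait,
            "significant_daps": {str(k): v for k, v in self.significant_daps.items()},
            "runs": [list(r) for r in self.runs],
            "transient": self.transient,
        }


def _runs_from_daps(daps: Iterable[int], gap_tolerance: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of consecutive DAPs; gaps <= gap_tolerance are bridged."""
    ds = sorted(set(int(d) for d in daps))
    if not ds:
        return []
    runs = [[ds[0], ds[0]]]
    for d in ds[1:]:
        if d - runs[-1][1] <= 1 + gap_tolerance:
            runs[-1][1] = d
        else:
            runs.append([d, d])
    return [tuple(r) for r in runs]


def detect_transient(
    hits: pd.DataFrame,
    final_dap: int | None = None,
    gap_tolerance: int = 0,
) -> list[TransientTrack]:
    """Assemble per-marker, per-trait significance tracks from the hit tensor.

    `hits` columns: marker, trait, DAP, tier.  A track is transient when it
    has more than one run or ends before `final_dap` (default: the maximum
    DAP present in `hits`).
    """
    if hits.empty:
        return []
    if final_dap is None:
        final_dap = int(hits["DAP"].max())
    tracks = []
    for (marker, trait), grp in hits.groupby(["marker", "trait"], sort=True):
        sig = {int(r.DAP): r.tier for r in grp.itertuples()}
        runs = _runs_from_daps(sig.keys(), gap_tolerance)
        transient = len(runs) > 1 or (runs and runs[-1][1] < final_dap)
        tracks.append(TransientTrack(marker, trait, sig, runs, transient))
    return tracks


def detect_pleiotropy(hits: pd.DataFrame) -> dict[str, dict[str, list[int]]]:
    """Markers significant for two or more traits, with their DAP sets."""
    if hits.empty:
        return {}
    out: dict[str, dict[str, list[int]]] = {}
    for marker, grp in hits.groupby("marker", sort=True):
        traits = {
            trait: sorted(int(d) for d in tg["DAP"].unique())
            for trait, tg in grp.groupby("trait", sort=True)
        }
        if len(traits) >= 2:
            out[marker] = traits
    return out


@dataclasses.dataclass
class AlleleEffectSeries:
    marker: str
    trait: str
    alleles: tuple[str, str]  # (ref-homozygote label, alt-homozygote label)
    table: pd.DataFrame  # per DAP: mean0, n0, mean2, n2, diff, p, hit_tier

    def direction(self) -> pd.Series:
        return np.sign(self.table["diff"])


def allele_effect_series(
    geno: GenotypeMatrix,
    traits_table: pd.DataFrame,
    marker: str,
    trait: str,
    hits: pd.DataFrame | None = None,
    min_class: int = 3,
) -> AlleleEffectSeries:
    """Per-DAP phenotype means by homozygous allele class at one marker.

    Computes group means and counts, the difference (alt - ref), and a Welch
    two-sample test p-value per DAP; the test is suppressed (NaN, with the
    series still reported) when a class has fewer than `min_class`
    accessions.  DAPs where the marker is a high-confidence GWAS hit are
    tagged with their tier when `hits` is given.
    """
    j = geno.markers.index[geno.markers["id"] == marker]
    if len(j) == 0:
        raise KeyError(f"marker {marker!r} not in genotype matrix")
    j = int(j[0])
    dos = geno.dosages[:, j]
    row = geno.markers.iloc[j]
    labels = (f"{row['ref']}{row['ref']}", f"{row['alt']}{row['alt']}")
    sub = traits_table[traits_table["trait"] == trait]
    wide = sub.pivot_table(index="accession", columns="DAP", values="value")
    acc_dos = pd.Series(dos, index=geno.accessions).reindex(wide.index)
    g0 = wide[acc_dos == 0]
    g2 = wide[acc_dos == 2]
    if len(g0) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 accessions in each homozygote class")
    tier_map = {}
    if hits is not None and not hits.empty:
        sel = hits[(hits["marker"] == marker) & (hits["trait"] == trait)]
        tier_map = {int(r.DAP): r.tier for r in sel.itertuples()}
    rows = []
    for dap in wide.columns:
        a, b = g0[dap].dropna(), g2[dap].dropna()
        mean0 = float(a.mean()) if len(a) else np.nan
        mean2 = float(b.mean()) if len(b) else np.nan
        if len(a) >= min_class and len(b) >= min_class and (a.var() + b.var()) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _t, p = stats.ttest_ind(b, a, equal_var=False)
            p = float(p)
            suppressed = False
        else:
            p, suppressed = np.nan, True
        rows.append(
            {
                "DAP": int(dap),
                "mean0": mean0,
                "n0": len(a),
                "mean2": mean2,
                "n2": len(b),
                "diff": mean2 - mean0,
                "p": p,
                "test_suppressed": suppressed,
                "hit_tier": tier_map.get(int(dap), ""),
            }
        )
    return AlleleEffectSeries(marker, trait, labels, pd.DataFrame(rows))
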