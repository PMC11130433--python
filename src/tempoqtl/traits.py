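"""Trait derivation and quality control for daily image-derived measurements.

Turns raw per-plant measurement tables (pixel counts from one top and two
side views, height and hull-area pixels, daily water, endpoint fresh weight)
into the five analysis traits: area, biomass, height, hull area, water use
efficiency (WUE) and relative growth rate (RGR), plus germination calls.

QC chain, in fixed order: gross-outlier removal (40 median absolute
deviations), loess smoothing of each plant's daily series, then the
replicate median per accession.  Outliers are flagged and removed, never
imputed.  The MAD fence is applied cross-sectionally (within one trait and
DAP, across plants): an image artifact is extreme relative to its cohort on
that day, whereas along a growth series the 40-MAD fence spans the whole
dynamic range and would mask early-season artifacts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "composite_area",
    "call_germination",
    "call_death",
    "exclude_failed",
    "remove_outliers",
    "loess_smooth",
    "calibrate_biomass",
    "compute_wue",
    "compute_rgr",
    "derive_traits",
    "TraitConfig",
]


@dataclasses.dataclass
class TraitConfig:
    """Tunable QC / derivation parameters."""

    mad_k: float = 40.0
    loess_span: float = 0.5
    loess_degree: int = 2
    scale_factors: list[tuple[int, int, float]] = dataclasses.field(
        default_factory=list
    )  # (start DAP, end DAP, factor); empty = 1.0 everywhere
    calibration_dap: int = 51
    exclusion_cutoff: int = 46
    min_germinated: int = 2
    death_zero_days: int = 5


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def composite_area(tv_px, sv1_px, sv2_px, scale_factor=1.0):
    """Composite plant area: (top view + both side views) x zoom scale factor.

    Scale factors make pixel counts comparable across optical-zoom changes.
    Inputs may be scalars or aligned arrays.
    """
    tv, sv1, sv2 = (np.asarray(v, dtype=float) for v in (tv_px, sv1_px, sv2_px))
    if np.any(tv < 0) or np.any(sv1 < 0) or np.any(sv2 < 0):
        raise ValueError("negative pixel count")
    scale = np.asarray(scale_factor, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale factor must be positive")
    return (tv + sv1 + sv2) * scale


def call_germination(top_view: pd.Series) -> float:
    """Germination DAP of one plant: earliest DAP with a positive top-view area.

    `top_view` is indexed by DAP.  Returns NaN if no positive value exists.
    """
    positive = top_view[top_view > 0]
    return float(positive.index.min()) if len(positive) else float("nan")


def call_death(
    top_view: pd.Series, germination_dap: float, zero_days: int = 5
) -> float:
    """Death DAP: start of the first run of `zero_days` consecutive zero
    top-view areas after germination.  NaN if the plant never 'dies'.
    """
    if np.isnan(germination_dap):
        return float("nan")
    s = top_view.sort_index()
    after = s[s.index > germination_dap]
    run_start, run_len = None, 0
    for dap, val in after.items():
        if val <= 0:
            run_start = dap if run_len == 0 else run_start
            run_len += 1
            if run_len >= zero_days:
                return float(run_start)
        else:
            run_len = 0
    return float("nan")


def exclude_failed(
    germination: pd.DataFrame,
    cutoff: int = 46,
    min_germinated: int = 2,
) -> list[str]:
    """Retained accessions after the germination/death exclusion rule.

    `germination` has one row per plant with columns (accession, germ_dap,
    death_dap).  A plant counts if it germinated (germ_dap not NaN, and not
    after `cutoff`) and did not die by `cutoff`.  An accession is retained
    when at least `min_germinated` plants count.
    """
    ok = (
        germination["germ_dap"].notna()
        & (germination["germ_dap"] <= cutoff)
        & (germination["death_dap"].isna() | (germination["death_dap"] > cutoff))
    )
    counts = germination.loc[ok].groupby("accession").size()
    return sorted(counts[counts >= min_germinated].index)


def remove_outliers(values: np.ndarray, k: float = 40.0) -> np.ndarray:
    """Boolean outlier mask under the k-MAD rule.

    x is an outlier iff |x - median| > k * MAD with MAD = median|x_i - median|.
    Degenerate series (MAD == 0) are left untouched: the fence is meant only
    for gross image artifacts and is undefined there.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        return np.zeros_like(x, dtype=bool)
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if mad == 0:
        return np.zeros_like(x, dtype=bool)
    mask = np.zeros_like(x, dtype=bool)
    mask[finite] = np.abs(x[finite] - med) > k * mad
    return mask


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression, evaluated at each x.

    Local quadratic by default (R's loess convention); falls back to the raw
    series (with a warning) when fewer than five points are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        warnings.warn("too few points for loess; returning series unchanged")
        return y.copy()
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    # pairwise distances, k-nearest tricube weights per evaluation point
    d = np.abs(x[:, None] - x[None, :])
    dmax = np.sort(d, axis=1)[:, k - 1]
    dmax = np.where(dmax == 0, 1.0, dmax)
    u = np.clip(d / dmax[:, None], 0.0, 1.0)
    W = (1.0 - u**3) ** 3
    # locally centered design per evaluation point (well conditioned); the
    # fitted value is then the local intercept
    p = degree + 1
    dx = x[None, :] - x[:, None]  # (n_eval, n_obs)
    D = np.stack([dx**q for q in range(p)], axis=-1)  # (n, n, p)
    WD = W[:, :, None] * D
    A = np.einsum("ijp,ijq->ipq", WD, D)
    bvec = np.einsum("ijp,j->ip", WD, y)
    # minute scale-respecting jitter guards exactly singular local systems
    diag = np.einsum("ipp->ip", A)
    A = A + 1e-12 * diag[:, None, :] * np.eye(p)
    coef = np.linalg.solve(A, bvec[..., None])[..., 0]
    return coef[:, 0]


def calibrate_biomass(
    areas: np.ndarray, fresh_weights: np.ndarray
) -> tuple[float, float, float]:
    """OLS calibration of endpoint fresh weight on area: (slope, intercept, r2).

    Applied downstream as biomass(DAP) = slope * area(DAP) + intercept,
    floored at zero.
    """
    a = np.asarray(areas, dtype=float)
    w = np.asarray(fresh_weights, dtype=float)
    ok = np.isfinite(a) & np.isfinite(w)
    a, w = a[ok], w[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(a) == 0:
        raise ValueError("zero variance in calibration areas")
    slope, intercept = np.polyfit(a, w, 1)
    pred = slope * a + intercept
    ss_res = np.sum((w - pred) ** 2)
    ss_tot = np.sum((w - w.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def compute_wue(area: pd.Series, water: pd.Series) -> pd.Series:
    """WUE(t) = area(t) / cumulative water through t; NaN when that sum is 0.

    Both series are indexed by DAP; water must cover every DAP up to each
    evaluation day.
    """
    if (water < 0).any():
        raise ValueError("negative water record")
    cum = water.sort_index().cumsum()
    aligned = cum.reindex(area.index)
    if aligned.isna().any():
        raise ValueError("water records do not cover all evaluation days")
    out = area / aligned.where(aligned > 0)
    return out


def compute_rgr(
    ln_areas_t1: Iterable[float],
    ln_areas_t2: Iterable[float],
    t1: float,
    t2: float,
) -> float:
    """RGR between two time points from replicate log areas.

    RGR = (mean ln W2 - mean ln W1) / (t2 - t1).  Non-finite log values
    (from nonpositive areas) are skipped; NaN when a side has none.
    """
    if not t2 > t1:
        raise ValueError("t2 must exceed t1")
    a1 = np.asarray(list(ln_areas_t1), dtype=float)
    a2 = np.asarray(list(ln_areas_t2), dtype=float)
    a1, a2 = a1[np.isfinite(a1)], a2[np.isfinite(a2)]
    if len(a1) == 0 or len(a2) == 0:
        return float("nan")
    return float((a2.mean() - a1.mean()) / (t2 - t1))


# ---------------------------------------------------------------------------
# pipeline: raw tables -> tidy accession-level trait series
# ---------------------------------------------------------------------------


def _scale_for_dap(daps: np.ndarray, cfg: TraitConfig) -> np.ndarray:
    scale = np.ones(len(daps))
    for start, end, factor in cfg.scale_factors:
        scale[(daps >= start) & (daps <= end)] = factor
    return scale


def derive_traits(
    pheno: pd.DataFrame,
    water: pd.DataFrame,
    cfg: TraitConfig | None = None,
    traits: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Full derivation: raw measurements -> tidy accession x trait x DAP table.

    Steps: composite area per plant/DAP; germination + death calls and the
    accession exclusion rule; cross-sectional 40-MAD outlier removal per
    trait and DAP; per-plant loess smoothing; replicate median; biomass
    calibration against endpoint fresh weight; WUE from cumulative water;
    daily RGR from consecutive-day replicate log areas.

    Returns long format (accession, trait, DAP, value).  `traits` restricts
    the output (any of area, height, hull_area, biomass, wue, rgr).
    """
    cfg = cfg or TraitConfig()
    wanted = set(traits) if traits is not None else {
        "area", "height", "hull_area", "biomass", "wue", "rgr"
    }
    need_area = bool(wanted & {"area", "biomass", "wue", "rgr"})

    wide = pheno.pivot_table(
        index=["plant_id", "accession", "replicate", "DAP"],
        columns="trait",
        values="value",
        aggfunc="first",
    ).reset_index()
    daps = wide["DAP"].to_numpy()
    scale = _scale_for_dap(daps, cfg)
    plant_traits = {}
    if need_area:
        wide["area"] = composite_area(
            wide["tv_px"].fillna(0), wide["sv1_px"].fillna(0),
            wide["sv2_px"].fillna(0), scale,
        )
        plant_traits["area"] = "area"
    if "height" in wanted:
        plant_traits["height"] = "height_px"
        wide["height"] = wide["height_px"] * _scale_for_dap(daps, cfg) ** 0.5
    if "hull_area" in wanted:
        plant_traits["hull_area"] = "hull_px"
        wide["hull_area"] = wide["hull_px"] * scale

    # germination / death / exclusion ------------------------------------
    tv = wide.pivot_table(index="plant_id", columns="DAP", values="tv_px")
    germ_rows = []
    acc_of_plant = wide.drop_duplicates("plant_id").set_index("plant_id")["accession"]
    for plant_id, row in tv.iterrows():
        g = call_germination(row)
        d = call_death(row, g, cfg.death_zero_days)
        germ_rows.append(
            {"plant_id": plant_id, "accession": acc_of_plant[plant_id],
             "germ_dap": g, "death_dap": d}
        )
    germination = pd.DataFrame(germ_rows)
    max_dap = int(wide["DAP"].max())
    cutoff = min(cfg.exclusion_cutoff, max_dap)
    retained = exclude_failed(germination, cutoff, cfg.min_germinated)
    wide = wide[wide["accession"].isin(retained)]
    germinated_plants = set(
        germination.loc[germination["germ_dap"].notna(), "plant_id"]
    )
    wide = wide[wide["plant_id"].isin(germinated_plants)]

    # cross-sectional MAD filter then per-plant loess ---------------------
    long = wide.melt(
        id_vars=["plant_id", "accession", "replicate", "DAP"],
        value_vars=[t for t in plant_traits],
        var_name="trait",
        value_name="value",
    ).dropna(subset=["value"])
    keep_mask = np.ones(len(long), dtype=bool)
    for (_trait, _dap), grp in long.groupby(["trait", "DAP"], sort=False):
        mask = remove_outliers(grp["value"].to_numpy(), cfg.mad_k)
        keep_mask[long.index.get_indexer(grp.index[mask])] = False
    long = long.loc[keep_mask]

    smoothed_frames = []
    for (plant_id, accession, replicate, trait), grp in long.groupby(
        ["plant_id", "accession", "replicate", "trait"], sort=False
    ):
        grp = grp.sort_values("DAP")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = loess_smooth(
                grp["DAP"].to_numpy(), grp["value"].to_numpy(),
                cfg.loess_span, cfg.loess_degree,
            )
        smoothed_frames.append(
            pd.DataFrame(
                {
                    "plant_id": plant_id,
                    "accession": accession,
                    "replicate": replicate,
                    "trait": trait,
                    "DAP": grp["DAP"].to_numpy(),
                    "value": np.clip(fitted, 0.0, None),
                }
            )
        )
    smooth = pd.concat(smoothed_frames, ignore_index=True)

    # replicate median -----------------------------------------------------
    med = (
        smooth.groupby(["accession", "trait", "DAP"], sort=True)["value"]
        .median()
        .reset_index()
    )
    out_frames = [med[med["trait"].isin(wanted)]]
    area_acc = med[med["trait"] == "area"].pivot(
        index="accession", columns="DAP", values="value"
    )

    # biomass calibration --------------------------------------------------
    if "biomass" in wanted:
        fw = pheno[pheno["trait"] == "fresh_weight_g"]
        fw_plant = fw.set_index("plant_id")["value"]
        cal_dap = min(cfg.calibration_dap, max_dap)
        area_plant = smooth[(smooth["trait"] == "area") & (smooth["DAP"] == cal_dap)]
        paired = area_plant.set_index("plant_id")["value"].to_frame("area")
        paired["fw"] = fw_plant
        paired = paired.dropna()
        paired = paired[paired["area"] > 0]
        slope, intercept, r2 = calibrate_biomass(
            paired["area"].to_numpy(), paired["fw"].to_numpy()
        )
        biomass = np.clip(slope * area_acc + intercept, 0.0, None)
        bm = biomass.stack().rename("value").reset_index()
        bm["trait"] = "biomass"
        out_frames.append(bm[["accession", "trait", "DAP", "value"]])

    # WUE -------------------------------------------------------------------
    if "wue" in wanted:
        wtr = water[water["plant_id"].isin(germinated_plants)].copy()
        wtr["accession"] = wtr["plant_id"].map(acc_of_plant)
        acc_water = (
            wtr.groupby(["accession", "DAP"])["water_g"].mean().unstack()
        )
        wue_rows = []
        for accession in area_acc.index:
            if accession not in acc_water.index:
                continue
            series = compute_wue(
                area_acc.loc[accession].dropna(), acc_water.loc[accession].dropna()
            )
            for dap, val in series.items():
                wue_rows.append(
                    {"accession": accession, "trait": "wue", "DAP": int(dap),
                     "value": val}
                )
        out_frames.append(pd.DataFrame(wue_rows))

    # RGR: consecutive-day pairs on replicate log areas ---------------------
    if "rgr" in wanted:
        area_rep = smooth[smooth["trait"] == "area"]
        with np.errstate(divide="ignore"):
            ln = area_rep.assign(ln=np.log(area_rep["value"].to_numpy()))
        ln.loc[~np.isfinite(ln["ln"]), "ln"] = np.nan
        lnmean = (
            ln.groupby(["accession", "DAP"])["ln"].mean().unstack()
        )
        rgr_rows = []
        for accession, row in lnmean.iterrows():
            idx = row.index.to_numpy()
            for j in range(len(idx) - 1):
                if idx[j + 1] != idx[j] + 1:
                    continue
                v1, v2 = row.iloc[j], row.iloc[j + 1]
                if np.isnan(v1) or np.isnan(v2):
                    continue
                rgr_rows.append(
                    {"accession": accession, "trait": "rgr", "DAP": int(idx[j]),
                     "value": v2 - v1}
                )
        out_frames.append(pd.DataFrame(rgr_rows))

    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["trait", "accession", "DAP"]).reset_index(drop=True)


def plant_level_smoothed(
    pheno: pd.DataFrame,
    cfg: TraitConfig | None = None,
    traits: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-plant smoothed values (pre-median), for heritability estimation.

    Same QC chain as `derive_traits` but stopping before replicate
    aggregation; returns (plant_id, accession, replicate, trait, DAP, value).
    """
    cfg = cfg or TraitConfig()
    wanted = set(traits) if traits is not None else {"area", "height", "hull_area"}
    wide = pheno.pivot_table(
        index=["plant_id", "accession", "replicate", "DAP"],
        columns="trait",
        values="value",
        aggfunc="first",
    ).reset_index()
    daps = wide["DAP"].to_numpy()
    scale = _scale_for_dap(daps, cfg)
    if "area" in wanted:
        wide["area"] = composite_area(
            wide["tv_px"].fillna(0), wide["sv1_px"].fillna(0),
            wide["sv2_px"].fillna(0), scale,
        )
    if "height" in wanted:
        wide["height"] = wide["height_px"]
    if "hull_area" in wanted:
        wide["hull_area"] = wide["hull_px"]
    tv = wide.pivot_table(index="plant_id", columns="DAP", values="tv_px")
    germinated = {
        pid for pid, row in tv.iterrows() if not np.isnan(call_germination(row))
    }
    wide = wide[wide["plant_id"].isin(germinated)]
    long = wide.melt(
        id_vars=["plant_id", "accession", "replicate", "DAP"],
        value_vars=sorted(t for t in wanted if t in wide.columns),
        var_name="trait",
        value_name="value",
    ).dropna(subset=["value"])
    keep_mask = np.ones(len(long), dtype=bool)
    for (_t, _d), grp in long.groupby(["trait", "DAP"], sort=False):
        mask = remove_outliers(grp["value"].to_numpy(), cfg.mad_k)
        keep_mask[long.index.get_indexer(grp.index[mask])] = False
    long = long.loc[keep_mask]
    frames = []
    for (pid, acc, rep, trait), grp in long.groupby(
        ["plant_id", "accession", "replicate", "trait"], sort=False
    ):
        grp = grp.sort_values("DAP")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = loess_smooth(
                grp["DAP"].to_numpy(), grp["value"].to_numpy(),
                cfg.loess_span, cfg.loess_degree,
            )
        frames.append(
            pd.DataFrame(
                {"plant_id": pid, "accession": acc, "replicate": rep,
                 "trait": trait, "DAP": grp["DAP"].to_numpy(),
                 "value": np.clip(fitted, 0.0, None)}
            )
        )
    return pd.concat(frames, ignore_index=True)
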