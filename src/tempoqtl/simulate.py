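"""Synthetic genotype / temporal-phenotype generator.

Emulates a replicated, image-based growth experiment on a structured panel of
inbred accessions: Balding-Nichols subpopulation genotypes, logistic shoot
growth whose rate follows a staged temperature schedule, planted QTL whose
effects are active only inside stated DAP windows, a kinship-structured
polygenic background, a gravimetric watering protocol, endpoint fresh weight,
non-germinating plants and injected gross outliers.  The planted ground truth
is recorded for parameter-recovery tests.

Growth model: each plant carries a logistic state z with A(t) = Amax *
sigmoid(z(t)); z advances each day by the current growth rate r_t =
r_base * phase_multiplier(temperature) + active rate-QTL effects, which is
the exact discrete solution of logistic growth under piecewise-constant
rates.  Camera views split the area 20/40/40 (top/side/side) with relative
measurement noise per view; height and hull area are monotone transforms of
area with independent noise.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .statgen import GenotypeMatrix, astle_balding_kinship

__all__ = [
    "QtlSpec",
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotation",
    "DEFAULT_TEMPERATURE_PHASES",
    "TEMPERATURE_RATE_MULTIPLIERS",
]

# Staged schedule of the emulated experiment: 15 C day/night for 31 days,
# 24/19 C for 7 days, 32/22 C for the final 18 days.
DEFAULT_TEMPERATURE_PHASES: list[tuple[int, int, float, float]] = [
    (1, 31, 15.0, 15.0),
    (32, 38, 24.0, 19.0),
    (39, 56, 32.0, 22.0),
]

# Growth-rate multiplier applied to the base logistic rate at each day
# temperature; no published rate/temperature law for this system, so these
# are package defaults (cold strongly suppresses elongation).
TEMPERATURE_RATE_MULTIPLIERS: dict[float, float] = {15.0: 0.35, 24.0: 0.7, 32.0: 1.0}

_VIEW_FRACTIONS = {"tv_px": 0.2, "sv1_px": 0.4, "sv2_px": 0.4}
# effective CV of the composite (tv+sv1+sv2) area given independent per-view
# relative noise: sqrt(0.2^2 + 0.4^2 + 0.4^2) = 0.6
_COMPOSITE_NOISE_FACTOR = float(np.sqrt(sum(f * f for f in _VIEW_FRACTIONS.values())))


@dataclasses.dataclass
class QtlSpec:
    """A planted QTL: per-allele effect on a growth parameter in a DAP window.

    mode 'growth_rate' adds effect_size * (dosage/2) to the daily logistic
    rate while t is in `window`; 'asymptote' shifts Amax (whole run);
    'additive_on_trait' adds directly to the named trait inside the window.
    """

    marker_index: int
    trait: str = "area"
    effect_size: float = 0.1
    window: tuple[int, int] = (1, 56)
    mode: str = "growth_rate"

    def __post_init__(self) -> None:
        if self.mode not in {"growth_rate", "asymptote", "additive_on_trait"}:
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        if self.window[0] > self.window[1]:
            raise ValueError("QTL window start after end")


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    n_accessions: int = 200
    n_subpops: int = 3
    fst: float = 0.1
    n_markers: int = 500
    n_chromosomes: int = 5
    n_replicates: int = 3
    n_days: int = 56
    temperature_phases: list[tuple[int, int, float, float]] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_TEMPERATURE_PHASES)
    )
    temp_multipliers: dict[float, float] = dataclasses.field(
        default_factory=lambda: dict(TEMPERATURE_RATE_MULTIPLIERS)
    )
    qtl_specs: list[QtlSpec] = dataclasses.field(default_factory=list)
    polygenic_h2: float = 0.3
    measurement_noise_sd: float = 0.05  # relative (CV) noise per camera view
    additive_noise_sd: float = 0.0  # extra absolute noise, area units
    late_noise_inflation: float = 1.0  # noise multiplier after overlap_day
    overlap_day: int = 42  # leaves overlap late in the run
    outlier_rate: float = 0.0
    outlier_factor: float = 50.0
    nongerm_rate: float = 0.05
    seed: int = 0
    # growth-curve scale parameters
    amax_mean: float = 400.0  # asymptotic composite area, area units
    amax_cv: float = 0.25  # accession-level lognormal CV of the asymptote
    r_base: float = 0.35  # logistic rate per day at the warmest phase
    rate_cv: float = 0.08  # accession-level lognormal CV of the base rate
    z0: float = -6.0  # logistic state at germination
    germ_day_base: int = 7
    accession_germ_sd: float = 2.0  # accession-level germination-date spread
    germ_jitter: int = 1  # plant germination day uniform in accession +/- jitter
    chrom_length: int = 60_000_000
    # watering / endpoint parameters
    target_mass_g: float = 1192.0  # carrier 342 g + saturation 250 g + pot 600 g
    evap_base_g: float = 20.0  # daily pot evaporation
    transp_per_area_g: float = 0.3  # daily transpiration per area unit
    fresh_weight_per_area: float = 0.25  # g fresh weight per area unit

    def validate(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0, 1)")
        if self.n_subpops > self.n_accessions:
            raise ValueError("more subpopulations than accessions")
        for frac, name in [
            (self.polygenic_h2, "polygenic_h2"),
            (self.outlier_rate, "outlier_rate"),
            (self.nongerm_rate, "nongerm_rate"),
        ]:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")
        if self.n_markers < len(self.qtl_specs):
            raise ValueError("fewer markers than planted QTL")
        phases = sorted(self.temperature_phases)
        if phases[0][0] != 1 or phases[-1][1] != self.n_days:
            raise ValueError("temperature phases must tile 1..n_days")
        for (s1, e1, *_), (s2, e2, *_) in zip(phases, phases[1:]):
            if s2 != e1 + 1:
                raise ValueError("temperature phases must tile 1..n_days without gaps")
        for q in self.qtl_specs:
            if not (1 <= q.window[0] <= q.window[1] <= self.n_days):
                raise ValueError("QTL window outside 1..n_days")

    def day_temperature(self) -> np.ndarray:
        """Day temperature for DAP 1..n_days."""
        temps = np.empty(self.n_days)
        for start, end, day_c, _night_c in self.temperature_phases:
            temps[start - 1 : end] = day_c
        return temps

    def rate_multipliers(self) -> np.ndarray:
        temps = self.day_temperature()
        try:
            return np.array([self.temp_multipliers[t] for t in temps])
        except KeyError as exc:
            raise ValueError(f"no rate multiplier for temperature {exc}") from exc


@dataclasses.dataclass
class SimTruth:
    """Planted parameters of a synthetic dataset, for recovery tests."""

    qtl_specs: list[QtlSpec]
    true_polygenic_h2: float
    subpop_assignments: dict[str, int]
    nongerminated: list[str]
    outliers: list[tuple[str, int, str]]  # (plant_id, DAP, measurement)
    germination_day: dict[str, int]
    polygenic_values: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "qtl_specs": [dataclasses.asdict(q) for q in self.qtl_specs],
            "true_polygenic_h2": self.true_polygenic_h2,
            "subpop_assignments": self.subpop_assignments,
            "nongerminated": self.nongerminated,
            "outliers": [list(t) for t in self.outliers],
            "germination_day": self.germination_day,
            "polygenic_values": self.polygenic_values,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            qtl_specs=[QtlSpec(**q) for q in d["qtl_specs"]],
            true_polygenic_h2=d["true_polygenic_h2"],
            subpop_assignments=d["subpop_assignments"],
            nongerminated=d["nongerminated"],
            outliers=[tuple(t) for t in d["outliers"]],
            germination_day={k: int(v) for k, v in d["germination_day"].items()},
            polygenic_values=d["polygenic_values"],
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Structured inbred genotypes under the Balding-Nichols model.

    Ancestral allele frequencies are Uniform(0.1, 0.9); each subpopulation
    draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) at F = cfg.fst;
    each inbred accession then draws a single allele per marker, so dosages
    are {0, 2}.  Markers receive sorted positions on cfg.n_chromosomes.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "genotypes")
    n, m = cfg.n_accessions, cfg.n_markers
    p_anc = rng.uniform(0.1, 0.9, size=m)
    F = cfg.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    subpop = np.arange(n) % cfg.n_subpops
    p_sub = rng.beta(a, b, size=(cfg.n_subpops, m))
    # one allele draw per inbred accession -> dosage 0 or 2
    dosages = 2.0 * (rng.random((n, m)) < p_sub[subpop, :])

    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    rows = []
    alleles = np.array(list("ACGT"))
    for c, idx in enumerate(per_chrom, start=1):
        # distinct random positions without materializing the whole range
        want = len(idx)
        pos = np.unique(rng.integers(1, cfg.chrom_length, size=2 * want + 16))
        while len(pos) < want:  # pragma: no cover - vanishingly unlikely
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, cfg.chrom_length, size=want)])
            )
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        for k, j in enumerate(idx):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "id": f"M{j:05d}",
                    "chrom": f"Chr{c:02d}",
                    "pos": int(pos[k]),
                    "ref": alleles[ref],
                    "alt": alleles[alt],
                }
            )
    markers = pd.DataFrame(rows)
    geno = GenotypeMatrix([f"ACC{i:04d}" for i in range(n)], markers, dosages)
    geno.subpop_assignments = {acc: int(s) for acc, s in zip(geno.accessions, subpop)}
    return geno


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _polygenic_background(geno: GenotypeMatrix, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance accession effects with covariance proportional to kinship."""
    p = geno.allele_freq()
    poly = (p > 0) & (p < 1)
    X = np.nan_to_num(geno.dosages[:, poly])
    pp = p[poly]
    Z = (X - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    K = Z @ Z.T / Z.shape[1]
    n = K.shape[0]
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    b = V @ (np.sqrt(w) * rng.standard_normal(n))
    sd = b.std()
    return b / sd if sd > 0 else b


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Daily measurement tables for every plant.

    Returns (pheno, water, truth): `pheno` is long-format with columns
    (plant_id, accession, replicate, DAP, trait, value) where trait is one of
    tv_px / sv1_px / sv2_px / height_px / hull_px / fresh_weight_g (the last
    only at the final DAP); `water` has (plant_id, DAP, water_g).
    """
    cfg.validate()
    for q in cfg.qtl_specs:
        if not (0 <= q.marker_index < geno.n_markers):
            raise ValueError(f"QTL marker index {q.marker_index} out of range")
    n = geno.n_accessions
    if n != cfg.n_accessions:
        raise ValueError("genotypes and config disagree on accession count")
    rng = child_rng(cfg.seed, "phenotypes")
    n_days = cfg.n_days
    days = np.arange(1, n_days + 1)

    # per-accession growth parameters ------------------------------------
    # accession-level diversity in asymptote, intrinsic rate and germination
    # date emulates the panel's genetic diversity in growth habit
    amax_factor = (
        rng.lognormal(-0.5 * cfg.amax_cv**2, cfg.amax_cv, size=n)
        if cfg.amax_cv > 0 else np.ones(n)
    )
    rate_factor = (
        rng.lognormal(-0.5 * cfg.rate_cv**2, cfg.rate_cv, size=n)
        if cfg.rate_cv > 0 else np.ones(n)
    )
    acc_germ = cfg.germ_day_base + (
        rng.normal(0.0, cfg.accession_germ_sd, size=n)
        if cfg.accession_germ_sd > 0 else np.zeros(n)
    )
    base_rate = cfg.r_base * cfg.rate_multipliers()  # (n_days,)
    rate = base_rate[None, :] * rate_factor[:, None]  # (n, n_days)
    amax = cfg.amax_mean * amax_factor
    additive = np.zeros((n, n_days))
    for q in cfg.qtl_specs:
        dose = np.nan_to_num(geno.dosages[:, q.marker_index]) / 2.0
        in_win = (days >= q.window[0]) & (days <= q.window[1])
        if q.mode == "growth_rate":
            rate[:, in_win] += q.effect_size * dose[:, None]
        elif q.mode == "asymptote":
            amax = amax + q.effect_size * dose
        else:  # additive_on_trait
            additive[:, in_win] += q.effect_size * dose[:, None]

    if cfg.polygenic_h2 > 0:
        b = _polygenic_background(geno, rng)
    else:
        b = np.zeros(n)
    # multiplicative genetic factor sized so that the composite-area
    # between:within ratio matches polygenic_h2 under pure CV noise
    h = cfg.polygenic_h2
    gamma = (
        _COMPOSITE_NOISE_FACTOR
        * cfg.measurement_noise_sd
        * np.sqrt(h / (1 - h))
        if h < 1
        else 0.0
    )
    gen_factor = 1.0 + gamma * b  # (n,)

    # plants --------------------------------------------------------------
    n_plants = n * cfg.n_replicates
    acc_idx = np.repeat(np.arange(n), cfg.n_replicates)
    rep_idx = np.tile(np.arange(1, cfg.n_replicates + 1), n)
    plant_ids = [
        f"{geno.accessions[a]}_r{r}" for a, r in zip(acc_idx, rep_idx)
    ]
    germ = np.clip(
        np.rint(acc_germ[acc_idx]).astype(int)
        + rng.integers(-cfg.germ_jitter, cfg.germ_jitter + 1, size=n_plants),
        2,
        max(cfg.n_days - 5, 2),
    )
    nongerm_mask = rng.random(n_plants) < cfg.nongerm_rate

    # logistic state per plant/day: z(t) = z0 + cumulative rate since germination
    rate_p = rate[acc_idx]  # (n_plants, n_days)
    active = days[None, :] > germ[:, None]  # rate applies after germination day
    csum = np.cumsum(rate_p * active, axis=1)
    z = cfg.z0 + csum
    area_true = amax[acc_idx, None] / (1.0 + np.exp(-z))
    area_true = area_true * gen_factor[acc_idx, None] + additive[acc_idx]
    area_true[days[None, :] < germ[:, None]] = 0.0
    area_true[nongerm_mask] = 0.0
    area_true = np.clip(area_true, 0.0, None)

    # measurement noise ----------------------------------------------------
    infl = np.where(days > cfg.overlap_day, cfg.late_noise_inflation, 1.0)
    cv = cfg.measurement_noise_sd * infl  # (n_days,)

    def noisy(frac_or_scale: np.ndarray, rel_sd: np.ndarray) -> np.ndarray:
        eps = rng.standard_normal(area_true.shape)
        add = cfg.additive_noise_sd * infl * rng.standard_normal(area_true.shape)
        out = frac_or_scale * (1.0 + rel_sd * eps) + add * (area_true > 0)
        return np.clip(out, 0.0, None)

    views = {}
    for name, frac in _VIEW_FRACTIONS.items():
        views[name] = noisy(frac * area_true, cv[None, :])
    height = noisy(15.0 * np.sqrt(area_true), 0.6 * cv[None, :])
    hull = noisy(2.2 * area_true**1.05, cv[None, :])
    measures = dict(views)
    measures["height_px"] = height
    measures["hull_px"] = hull

    # injected gross outliers ---------------------------------------------
    outliers: list[tuple[str, int, str]] = []
    if cfg.outlier_rate > 0:
        names = list(measures)
        for mi, name in enumerate(names):
            M = measures[name]
            eligible = np.nonzero(M > 0)
            n_cells = len(eligible[0])
            n_out = rng.binomial(n_cells, cfg.outlier_rate)
            if n_out == 0:
                continue
            pick = rng.choice(n_cells, size=n_out, replace=False)
            rr, cc = eligible[0][pick], eligible[1][pick]
            M[rr, cc] *= cfg.outlier_factor
            outliers.extend(
                (plant_ids[r], int(days[c]), name) for r, c in zip(rr, cc)
            )

    # watering: twice-daily top-up to the target mass; the deficit each day
    # is evaporation plus size-dependent transpiration
    et = (
        cfg.evap_base_g
        + cfg.transp_per_area_g * area_true
        + 2.0 * rng.standard_normal(area_true.shape)
    )
    water = np.clip(et, 0.0, None)

    # endpoint fresh weight (germinated plants only)
    fw = cfg.fresh_weight_per_area * area_true[:, -1] * (
        1.0 + 0.05 * rng.standard_normal(n_plants)
    )
    fw = np.clip(fw, 0.0, None)

    # assemble long tables -------------------------------------------------
    frames = []
    acc_names = np.array(geno.accessions)[acc_idx]
    for name, M in measures.items():
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": np.repeat(plant_ids, n_days),
                    "accession": np.repeat(acc_names, n_days),
                    "replicate": np.repeat(rep_idx, n_days),
                    "DAP": np.tile(days, n_plants),
                    "trait": name,
                    "value": M.ravel(),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "plant_id": plant_ids,
                "accession": acc_names,
                "replicate": rep_idx,
                "DAP": n_days,
                "trait": "fresh_weight_g",
                "value": fw,
            }
        )
    )
    pheno = pd.concat(frames, ignore_index=True)
    water_df = pd.DataFrame(
        {
            "plant_id": np.repeat(plant_ids, n_days),
            "DAP": np.tile(days, n_plants),
            "water_g": water.ravel(),
        }
    )
    subpops = getattr(geno, "subpop_assignments", None) or {
        a: 0 for a in geno.accessions
    }
    truth = SimTruth(
        qtl_specs=list(cfg.qtl_specs),
        true_polygenic_h2=cfg.polygenic_h2,
        subpop_assignments=subpops,
        nongerminated=[p for p, m in zip(plant_ids, nongerm_mask) if m],
        outliers=outliers,
        germination_day={
            p: (0 if m else int(g))
            for p, g, m in zip(plant_ids, germ, nongerm_mask)
        },
        polygenic_values={a: float(v) for a, v in zip(geno.accessions, b)},
    )
    return pheno, water_df, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    geno: GenotypeMatrix, genes_per_chrom: int, seed: int
) -> pd.DataFrame:
    """Toy non-overlapping gene models as a GFF3-ready table.

    Genes are placed per chromosome without overlap; a subset is centered on
    randomly chosen markers so the downstream window scan always has hits.
    Returns a DataFrame (gene_id, chrom, start, end, strand).
    """
    rng = child_rng(seed, "annotation")
    rows = []
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        if genes_per_chrom == 0:
            continue
        span = int(grp["pos"].max()) + 50_000
        lengths = np.clip(
            rng.normal(3000, 1000, size=genes_per_chrom), 500, 10_000
        ).astype(int)
        # half of the genes sit on markers, the rest are placed at random
        n_on_marker = max(1, genes_per_chrom // 2)
        centers = list(
            rng.choice(grp["pos"].to_numpy(), size=min(n_on_marker, len(grp)), replace=False)
        )
        centers += list(
            rng.integers(1, span, size=genes_per_chrom - len(centers))
        )
        intervals = []
        for c, ln in zip(sorted(int(c) for c in centers), lengths):
            start = max(1, c - ln // 2)
            end = start + ln - 1
            if intervals and start <= intervals[-1][1]:
                start = intervals[-1][1] + 1 + int(rng.integers(100, 2000))
                end = start + ln - 1
            intervals.append((start, end))
        for k, (start, end) in enumerate(intervals):
            rows.append(
                {
                    "gene_id": f"Gene_{chrom}_{k:04d}",
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
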