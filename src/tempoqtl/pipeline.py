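"""End-to-end pipeline orchestration with caching and a run manifest.

Stages (dependency order): simulate -> traits -> heritability -> cluster ->
ideotype -> gwas -> transient -> annotate.  Each stage reads its inputs from
files in the output directory and writes its outputs there; a stage is
skipped when its parameter/input fingerprint matches the previous run's
manifest and its outputs still exist.  The manifest records the tool
version, config hash, per-stage checksums and warnings, so identical
configs reproduce identical checksums for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import annotate as annotate_mod
from . import longitudinal, profiles, simulate, statgen, traits as traits_mod

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "water_budget_check"]

STAGES = [
    "simulate",
    "traits",
    "heritability",
    "cluster",
    "ideotype",
    "gwas",
    "transient",
    "annotate",
]


def water_budget_check(carrier_g: float, saturation_g: float, pot_g: float) -> float:
    """Gravimetric watering target: carrier + water at saturation + filled pot.

    With the study's components (342 g carrier, 250 g water at saturation,
    600 g Turface-filled pot) this is the 1192 g target mass the plants were
    watered to twice daily.
    """
    parts = (carrier_g, saturation_g, pot_g)
    if any(p < 0 for p in parts):
        raise ValueError("mass components must be nonnegative")
    return float(sum(parts))


@dataclasses.dataclass
class RunConfig:
    """Flat, schema-validated pipeline configuration.

    Defaults reproduce the study's analysis parameters: 3 genotype PCs,
    alpha 0.05, MAF > 0.05, 40-MAD outlier fence, 15 kb candidate window,
    clustering over DAP 12-56, ideotype windows 15-31 / 39-56 with 5% / 10%
    thresholds, biomass calibration at 51 DAP and exclusion at 46 DAP.
    """

    seed: int = 0
    # simulation
    n_accessions: int = 200
    n_subpops: int = 3
    fst: float = 0.1
    n_markers: int = 500
    n_chromosomes: int = 5
    n_replicates: int = 3
    n_days: int = 56
    temperature_phases: list = dataclasses.field(
        default_factory=lambda: [list(p) for p in simulate.DEFAULT_TEMPERATURE_PHASES]
    )
    polygenic_h2: float = 0.3
    measurement_noise_sd: float = 0.05
    outlier_rate: float = 0.005
    nongerm_rate: float = 0.05
    qtl: list = dataclasses.field(default_factory=list)  # dicts: QtlSpec fields
    genes_per_chrom: int = 40
    # trait derivation
    mad_k: float = 40.0
    loess_span: float = 0.5
    calibration_dap: int = 51
    exclusion_cutoff: int = 46
    # analysis
    maf_min: float = 0.05
    n_pcs: int = 3
    alpha: float = 0.05
    k_clusters: int = 7
    cluster_trait: str = "wue"
    cluster_dap_min: int = 12
    cluster_dap_max: int = 56
    ideotype_early: list = dataclasses.field(default_factory=lambda: [15, 31])
    ideotype_late: list = dataclasses.field(default_factory=lambda: [39, 56])
    ideotype_wue_top: float = 90.0
    ideotype_ratio_bottom: float = 5.0
    gwas_traits: list = dataclasses.field(default_factory=lambda: ["area"])
    gwas_daps: list | None = None  # None = every DAP
    scan_window_bp: int = 15000
    stages: list = dataclasses.field(default_factory=lambda: list(STAGES))

    @classmethod
    def demo(cls, seed: int = 0) -> "RunConfig":
        """Small configuration that completes end-to-end in seconds."""
        return cls(
            seed=seed,
            n_accessions=40,
            n_markers=120,
            n_chromosomes=3,
            n_days=30,
            temperature_phases=[[1, 18, 15.0, 15.0], [19, 24, 24.0, 19.0],
                                [25, 30, 32.0, 22.0]],
            nongerm_rate=0.03,
            genes_per_chrom=15,
            calibration_dap=25,
            cluster_dap_min=12,
            cluster_dap_max=30,
            k_clusters=3,
            ideotype_early=[10, 18],
            ideotype_late=[25, 30],
            gwas_daps=[15, 22, 30],
            qtl=[{"marker_index": 10, "trait": "area", "effect_size": 0.15,
                  "window": [12, 22], "mode": "growth_rate"}],
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_accessions=self.n_accessions,
            n_subpops=self.n_subpops,
            fst=self.fst,
            n_markers=self.n_markers,
            n_chromosomes=self.n_chromosomes,
            n_replicates=self.n_replicates,
            n_days=self.n_days,
            temperature_phases=[tuple(p) for p in self.temperature_phases],
            qtl_specs=[
                simulate.QtlSpec(
                    marker_index=q["marker_index"],
                    trait=q.get("trait", "area"),
                    effect_size=q.get("effect_size", 0.1),
                    window=tuple(q.get("window", (1, self.n_days))),
                    mode=q.get("mode", "growth_rate"),
                )
                for q in self.qtl
            ],
            polygenic_h2=self.polygenic_h2,
            measurement_noise_sd=self.measurement_noise_sd,
            outlier_rate=self.outlier_rate,
            nongerm_rate=self.nongerm_rate,
            seed=self.seed,
        )

    def trait_config(self) -> traits_mod.TraitConfig:
        return traits_mod.TraitConfig(
            mad_k=self.mad_k,
            loess_span=self.loess_span,
            calibration_dap=self.calibration_dap,
            exclusion_cutoff=self.exclusion_cutoff,
        )


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict[str, dict[str, Any]]  # stage -> {key, outputs: {path: sha}, time}
    warnings: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["version"], d["config_hash"], d["stages"], d["warnings"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# config fields each stage actually depends on, so unrelated parameter
# changes never invalidate a cached stage
_STAGE_PARAMS = {
    "simulate": [
        "seed", "n_accessions", "n_subpops", "fst", "n_markers",
        "n_chromosomes", "n_replicates", "n_days", "temperature_phases",
        "polygenic_h2", "measurement_noise_sd", "outlier_rate",
        "nongerm_rate", "qtl", "genes_per_chrom",
    ],
    "traits": ["mad_k", "loess_span", "calibration_dap", "exclusion_cutoff"],
    "heritability": ["n_replicates"],
    "cluster": ["k_clusters", "cluster_trait", "cluster_dap_min", "cluster_dap_max"],
    "ideotype": [
        "ideotype_early", "ideotype_late", "ideotype_wue_top",
        "ideotype_ratio_bottom",
    ],
    "gwas": ["maf_min", "n_pcs", "alpha", "gwas_traits", "gwas_daps"],
    "transient": [],
    "annotate": ["scan_window_bp"],
}


def _stage_key(cfg: RunConfig, stage: str, input_files: list[Path]) -> str:
    d = dataclasses.asdict(cfg)
    params = {k: d[k] for k in _STAGE_PARAMS[stage]}
    payload = json.dumps(
        {
            "stage": stage,
            "config": params,
            "inputs": {str(p): _sha256(p) for p in sorted(input_files)},
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, outdir) -> RunManifest:
    """Execute the configured stages, reusing cached outputs when possible."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    prev = (
        RunManifest.from_json(manifest_path) if manifest_path.exists() else None
    )
    stages_record: dict[str, dict[str, Any]] = {}
    warnings_log: list[str] = []

    paths = {
        "geno_vcf": out / "geno.vcf",
        "geno_tsv": out / "geno.tsv",
        "pheno": out / "pheno.csv",
        "water": out / "water.csv",
        "gff": out / "genes.gff3",
        "truth": out / "truth.json",
        "traits": out / "traits.tsv",
        "plant_traits": out / "plant_traits.tsv",
        "h2": out / "h2.tsv",
        "clusters": out / "clusters.tsv",
        "cluster_means": out / "cluster_means.tsv",
        "ideotype": out / "ideotype.json",
        "hits": out / "hits.tsv",
        "gwas_summary": out / "gwas_summary.json",
        "tracks": out / "tracks.json",
        "pleiotropy": out / "pleiotropy.json",
        "candidates": out / "candidates.tsv",
    }

    stage_io = {
        "simulate": ([], ["geno_vcf", "geno_tsv", "pheno", "water", "gff", "truth"]),
        "traits": (["pheno", "water"], ["traits", "plant_traits"]),
        "heritability": (["plant_traits"], ["h2"]),
        "cluster": (["traits"], ["clusters", "cluster_means"]),
        "ideotype": (["traits"], ["ideotype"]),
        "gwas": (["geno_tsv", "traits"], ["hits", "gwas_summary"]),
        "transient": (["hits"], ["tracks", "pleiotropy"]),
        "annotate": (["hits", "gff"], ["candidates"]),
    }

    def ready(stage: str) -> None:
        inputs, _ = stage_io[stage]
        missing = [k for k in inputs if not paths[k].exists()]
        if missing:
            raise RuntimeError(
                f"stage '{stage}' is missing inputs {missing}; run the producing "
                "stage first"
            )

    def cached(stage: str, key: str) -> bool:
        if prev is None or stage not in prev.stages:
            return False
        rec = prev.stages[stage]
        if rec["key"] != key:
            return False
        return all(Path(p).exists() for p in rec["outputs"])

    def finish(stage: str, key: str, t0: float) -> None:
        _, outputs = stage_io[stage]
        stages_record[stage] = {
            "key": key,
            "outputs": {str(paths[k]): _sha256(paths[k]) for k in outputs},
            "seconds": round(time.time() - t0, 3),
        }

    for stage in STAGES:
        if stage not in cfg.stages:
            if prev is not None and stage in prev.stages:
                stages_record[stage] = prev.stages[stage]
            continue
        ready(stage)
        inputs, _ = stage_io[stage]
        key = _stage_key(cfg, stage, [paths[k] for k in inputs])
        t0 = time.time()
        if cached(stage, key):
            stages_record[stage] = prev.stages[stage]
            continue
        _run_stage(stage, cfg, paths, warnings_log)
        finish(stage, key, t0)

    manifest = RunManifest(__version__, cfg.hash(), stages_record, warnings_log)
    manifest.to_json(manifest_path)
    return manifest


def _run_stage(stage: str, cfg: RunConfig, paths: dict, warnings_log: list) -> None:
    if stage == "simulate":
        sim_cfg = cfg.sim_config()
        geno = simulate.simulate_genotypes(sim_cfg)
        pheno, water, truth = simulate.simulate_phenotypes(geno, sim_cfg)
        genes = simulate.simulate_annotation(geno, cfg.genes_per_chrom, cfg.seed)
        geno.to_vcf(paths["geno_vcf"])
        geno.to_tsv(paths["geno_tsv"])
        pheno.to_csv(paths["pheno"], index=False)
        water.to_csv(paths["water"], index=False)
        annotate_mod.write_gff3(genes, paths["gff"])
        truth.to_json(paths["truth"])

    elif stage == "traits":
        pheno = pd.read_csv(paths["pheno"])
        water = pd.read_csv(paths["water"])
        tcfg = cfg.trait_config()
        tidy = traits_mod.derive_traits(pheno, water, tcfg)
        tidy.to_csv(paths["traits"], sep="\t", index=False)
        plant = traits_mod.plant_level_smoothed(pheno, tcfg)
        plant.to_csv(paths["plant_traits"], sep="\t", index=False)
        n_acc = tidy["accession"].nunique()
        warnings_log.append(f"traits: {n_acc} accessions retained after exclusion")

    elif stage == "heritability":
        plant = pd.read_csv(paths["plant_traits"], sep="\t")
        rows = []
        for (trait, dap), grp in plant.groupby(["trait", "DAP"]):
            vals = grp.pivot_table(
                index="accession", columns="replicate", values="value"
            )
            try:
                res = statgen.heritability(
                    vals, trait, int(dap), cfg.n_replicates
                )
            except ValueError:
                continue
            rows.append(
                {
                    "trait": trait,
                    "DAP": int(dap),
                    "sigma2_genotype": res.sigma2_genotype,
                    "sigma2_error": res.sigma2_error,
                    "H2": res.h2,
                    "n_accessions": res.n_accessions,
                }
            )
        pd.DataFrame(rows).to_csv(paths["h2"], sep="\t", index=False)

    elif stage == "cluster":
        tidy = pd.read_csv(paths["traits"], sep="\t")
        prof = tidy[tidy["trait"] == cfg.cluster_trait].pivot_table(
            index="accession", columns="DAP", values="value"
        )
        k = min(cfg.k_clusters, len(prof))
        res = profiles.cluster_profiles(
            prof, k, (cfg.cluster_dap_min, cfg.cluster_dap_max)
        )
        res.assignments.rename("cluster").to_csv(paths["clusters"], sep="\t")
        res.mean_profiles.to_csv(paths["cluster_means"], sep="\t")

    elif stage == "ideotype":
        tidy = pd.read_csv(paths["traits"], sep="\t")
        wide = {
            t: tidy[tidy["trait"] == t].pivot_table(
                index="accession", columns="DAP", values="value"
            )
            for t in ("wue", "height", "biomass")
        }
        ratio = wide["height"] / wide["biomass"].where(wide["biomass"] > 0)
        wue_pct = profiles.percentile_table(wide["wue"])
        ratio_pct = profiles.percentile_table(ratio)
        report = {}
        for name, window in (
            ("early", tuple(cfg.ideotype_early)),
            ("late", tuple(cfg.ideotype_late)),
        ):
            rep = profiles.select_ideotypes(
                wue_pct, ratio_pct, window,
                wue_top=cfg.ideotype_wue_top,
                ratio_bottom=cfg.ideotype_ratio_bottom,
            )
            report[name] = rep.to_dict()
        with open(paths["ideotype"], "w") as fh:
            json.dump(report, fh, indent=1)

    elif stage == "gwas":
        geno = statgen.GenotypeMatrix.from_tsv(paths["geno_tsv"])
        tidy = pd.read_csv(paths["traits"], sep="\t")
        gcfg = longitudinal.GwasConfig(
            n_pcs=cfg.n_pcs, maf_min=cfg.maf_min, alpha=cfg.alpha
        )
        fits_by_trait = {}
        summary = {}
        for trait in cfg.gwas_traits:
            fits = longitudinal.longitudinal_gwas(
                geno, tidy, trait, cfg.gwas_daps, gcfg
            )
            fits_by_trait[trait] = fits
            summary[trait] = {
                str(dap): {
                    "pseudo_h2_null": res.steps[0].varcomp.pseudo_h2,
                    "path_length": len(res.steps) - 1,
                    "mbonf": sorted(res.mbonf),
                    "extbic": sorted(res.extbic),
                }
                for dap, res in fits.items()
            }
        hits = longitudinal.hits_table(fits_by_trait)
        hits.to_csv(paths["hits"], sep="\t", index=False)
        with open(paths["gwas_summary"], "w") as fh:
            json.dump(summary, fh, indent=1)

    elif stage == "transient":
        hits = pd.read_csv(paths["hits"], sep="\t")
        tracks = longitudinal.detect_transient(hits)
        with open(paths["tracks"], "w") as fh:
            json.dump([t.to_dict() for t in tracks], fh, indent=1)
        pleio = longitudinal.detect_pleiotropy(hits)
        with open(paths["pleiotropy"], "w") as fh:
            json.dump(pleio, fh, indent=1)

    elif stage == "annotate":
        hits = pd.read_csv(paths["hits"], sep="\t")
        annot = annotate_mod.GeneAnnotation.from_gff3(paths["gff"])
        geno = statgen.GenotypeMatrix.from_tsv(paths["geno_tsv"])
        meta = geno.markers.set_index("id")
        if hits.empty:
            report = pd.DataFrame(
                columns=["marker", "chrom", "pos", "gene_id", "distance_bp",
                         "relation", "strand"]
            )
        else:
            mk = hits[["marker"]].drop_duplicates()
            mk["chrom"] = mk["marker"].map(meta["chrom"])
            mk["pos"] = mk["marker"].map(meta["pos"])
            report = annotate_mod.scan_window(mk, annot, cfg.scan_window_bp)
        report.to_csv(paths["candidates"], sep="\t", index=False)

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
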