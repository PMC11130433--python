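"""Simulation experiments that validate the statistical machinery.

Each function runs a self-contained experiment at a fixed, documented
problem size and returns the measured quantity: oracle agreement of the
mixed-model scan, familywise error of the multiple-Bonferroni model under
the null, power to recover a planted additive QTL, end-to-end recovery of a
transient growth-rate QTL, heritability and Box-Cox parameter recovery,
clustering and ideotype agreement, candidate-window oracle agreement, and
the MAD outlier filter's operating characteristics.  These experiments are
shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from . import profiles, traits as traits_mod
from .annotate import GeneAnnotation, scan_window
from .longitudinal import GwasConfig, longitudinal_gwas
from .mlmm import MixedLMM, kinship_eigendecomposition, scan_markers
from .simulate import QtlSpec, SimConfig, simulate_genotypes, simulate_phenotypes
from .statgen import (
    astle_balding_kinship,
    boxcox_transform,
    genotype_pca,
    heritability,
    maf_filter_impute,
)

__all__ = [
    "scan_oracle_max_abs_diff",
    "mbonf_familywise_error",
    "planted_qtl_first_cofactor_rate",
    "transient_recovery",
    "heritability_recovery_mean",
    "boxcox_recovery",
    "rgr_exponential_max_error",
    "clustering_recovery_ari",
    "ideotype_brute_force_mismatches",
    "candidate_window_mismatches",
    "mad_filter_performance",
    "pick_marker_near_maf",
]


def pick_marker_near_maf(geno, target: float = 0.4) -> int:
    """Index of the marker whose realized MAF is closest to `target`."""
    maf = geno.compute_maf()
    return int(np.argmin(np.abs(maf - target)))


def _structured_genotypes(seed: int, n: int, m: int, label: str):
    cfg = SimConfig(
        n_accessions=n, n_subpops=3, fst=0.1, n_markers=m, n_chromosomes=5,
        seed=int(child_rng(seed, label).integers(2**31)),
    )
    geno = simulate_genotypes(cfg)
    return maf_filter_impute(geno)


# ---------------------------------------------------------------------------
# mixed-model scan oracle
# ---------------------------------------------------------------------------


def _gls_pvalues_explicit(y, X, K, sigma2_g, sigma2_e, G) -> np.ndarray:
    """Brute-force GLS F-tests with an explicit per-marker covariance solve."""
    n = len(y)
    Sigma = sigma2_g * K + sigma2_e * np.eye(n)
    L = np.linalg.cholesky(Sigma)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    Gw = np.linalg.solve(L, G)
    pvals = np.empty(G.shape[1])
    for j in range(G.shape[1]):
        Xa = np.column_stack([Xw, Gw[:, j]])
        q = Xa.shape[1]
        beta0, rss0_, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        beta1, rss1_, *_ = np.linalg.lstsq(Xa, yw, rcond=None)
        rss0 = float(np.sum((yw - Xw @ beta0) ** 2))
        rss1 = float(np.sum((yw - Xa @ beta1) ** 2))
        df = n - q
        f = (rss0 - rss1) / (rss1 / df)
        pvals[j] = stats.f.sf(f, 1, df)
    return pvals


def scan_oracle_max_abs_diff(seed: int, n: int = 50, m: int = 200) -> float:
    """Max |p_spectral - p_explicit| over one random instance (n x m)."""
    geno = _structured_genotypes(seed, n, m, "scan-oracle")
    K = astle_balding_kinship(geno)
    rng = child_rng(seed, "scan-oracle-y")
    d, U = kinship_eigendecomposition(K)
    g = U @ (np.sqrt(d) * rng.standard_normal(n))
    y = g + rng.standard_normal(n)
    X = np.column_stack([np.ones(n), genotype_pca(geno, 3).to_numpy()])
    from .mlmm import reml_variance_components

    vc = reml_variance_components(y, X, K)
    res = scan_markers(y, X, K, vc, geno.dosages)
    oracle = _gls_pvalues_explicit(
        y, X, K.values, vc.sigma2_g, vc.sigma2_e, geno.dosages
    )
    return float(np.max(np.abs(res.pvalues - oracle)))


# ---------------------------------------------------------------------------
# model selection: familywise error and power
# ---------------------------------------------------------------------------


def mbonf_familywise_error(
    seed: int, n_runs: int = 200, n: int = 100, m: int = 500
) -> float:
    """% of pure-noise runs in which the mBonf model selects >= 1 marker."""
    hits = 0
    for run in range(n_runs):
        geno = _structured_genotypes(seed + 1000 * run, n, m, "fwe-geno")
        K = astle_balding_kinship(geno)
        k_eig = kinship_eigendecomposition(K)
        pcs = genotype_pca(geno, 3).to_numpy()
        rng = child_rng(seed + 1000 * run, "fwe-y")
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), pcs])
        model = MixedLMM(y, X, None, geno.dosages, geno.markers[["id", "chrom", "pos"]],
                         k_eig=k_eig)
        res = model.fit(m_effective=geno.n_markers)
        if len(res.mbonf) >= 1:
            hits += 1
    return 100.0 * hits / n_runs


def planted_qtl_first_cofactor_rate(
    seed: int,
    n_runs: int = 100,
    n: int = 200,
    m: int = 500,
    var_explained: float = 0.225,
) -> float:
    """% of runs where a planted additive QTL is the first forward cofactor.

    The planted marker explains `var_explained` of phenotypic variance
    (default 22.5%, the middle of the 20-25% planting band).
    """
    first = 0
    for run in range(n_runs):
        geno = _structured_genotypes(seed + 1000 * run, n, m, "power-geno")
        j = pick_marker_near_maf(geno, 0.4)
        g = geno.dosages[:, j]
        gv = np.var(g)
        beta = np.sqrt(var_explained / (1.0 - var_explained) / gv)
        rng = child_rng(seed + 1000 * run, "power-y")
        y = beta * g + rng.standard_normal(n)
        K = astle_balding_kinship(geno)
        pcs = genotype_pca(geno, 3).to_numpy()
        X = np.column_stack([np.ones(n), pcs])
        model = MixedLMM(
            y, X, None, geno.dosages, geno.markers[["id", "chrom", "pos"]],
            k_eig=kinship_eigendecomposition(K),
        )
        res = model.fit(m_effective=geno.n_markers)
        if res.cofactors and res.cofactors[0] == geno.markers["id"].iloc[j]:
            first += 1
    return 100.0 * first / n_runs


# ---------------------------------------------------------------------------
# end-to-end transient QTL recovery
# ---------------------------------------------------------------------------


def _transient_config(seed: int, n: int, m: int, n_days: int) -> SimConfig:
    return SimConfig(
        n_accessions=n,
        n_subpops=3,
        fst=0.1,
        n_markers=m,
        n_chromosomes=5,
        n_replicates=3,
        n_days=n_days,
        temperature_phases=[
            (1, 31, 15.0, 15.0),
            (32, 38, 24.0, 19.0),
            (39, n_days, 32.0, 22.0),
        ],
        polygenic_h2=0.3,
        measurement_noise_sd=0.05,
        outlier_rate=0.005,
        nongerm_rate=0.02,
        seed=seed,
    )


def transient_recovery(
    seed: int,
    n_runs: int = 20,
    n: int = 200,
    m: int = 500,
    n_days: int = 45,
    window: tuple[int, int] = (20, 30),
    effect_size: float = 0.08,
) -> dict:
    """End-to-end recovery of a growth-rate QTL active only in a DAP window.

    Each run simulates genotypes + daily phenotypes (the QTL boosts the
    logistic growth rate of carriers only inside `window`), derives the area
    trait through the full QC chain, fits the per-day mixed model, and
    records the DAPs at which the planted marker is a high-confidence hit.
    Success = the significant-DAP set intersects [window_start, window_end+5]
    and contains nothing before DAP 15 (a rate effect leaves a persistent
    level difference, so significance may outlast the window but must not
    precede it).
    """
    successes = 0
    onset_daps: list[int] = []
    sig_sets: list[list[int]] = []
    for run in range(n_runs):
        run_seed = int(child_rng(seed + run, "transient-run").integers(2**31))
        cfg = _transient_config(run_seed, n, m, n_days)
        geno = simulate_genotypes(cfg)
        j = pick_marker_near_maf(geno, 0.4)
        cfg.qtl_specs = [
            QtlSpec(marker_index=j, trait="area", effect_size=effect_size,
                    window=window, mode="growth_rate")
        ]
        pheno, water, _truth = simulate_phenotypes(geno, cfg)
        tidy = traits_mod.derive_traits(pheno, water, traits=["area"])
        fits = longitudinal_gwas(geno, tidy, "area", config=GwasConfig())
        marker_id = geno.markers["id"].iloc[j]
        sig = sorted(
            dap for dap, res in fits.items() if marker_id in res.high_confidence
        )
        sig_sets.append(sig)
        in_band = [d for d in sig if window[0] <= d <= window[1] + 5]
        early = [d for d in sig if d < 15]
        if in_band and not early:
            successes += 1
            onset_daps.append(min(in_band))
    return {
        "success_rate_pct": 100.0 * successes / n_runs,
        "mean_onset_dap": float(np.mean(onset_daps)) if onset_daps else float("nan"),
        "significant_daps": sig_sets,
    }


# ---------------------------------------------------------------------------
# parameter recovery: heritability, Box-Cox, RGR
# ---------------------------------------------------------------------------


def heritability_recovery_mean(
    seed: int,
    n_reps: int = 100,
    n_accessions: int = 300,
    n_replicates: int = 3,
    true_h2: float = 0.5,
) -> float:
    """Mean H2 estimate when genetic and residual variances are equal."""
    rng = child_rng(seed, "h2-recovery")
    ratio = true_h2 / (1.0 - true_h2)
    ests = []
    for _ in range(n_reps):
        g = rng.normal(0.0, np.sqrt(ratio), size=n_accessions)
        y = g[:, None] + rng.standard_normal((n_accessions, n_replicates))
        df = pd.DataFrame(y, index=[f"A{i}" for i in range(n_accessions)])
        ests.append(heritability(df, n_replicates=n_replicates).h2)
    return float(np.mean(ests))


def boxcox_recovery(seed: int, n_reps: int = 50, n: int = 500) -> dict:
    """Mean lambda estimates for lognormal (true 0) and normal (true 1) data."""
    rng = child_rng(seed, "boxcox")
    lam_log, lam_norm = [], []
    for _ in range(n_reps):
        lam, _ = boxcox_transform(rng.lognormal(0.0, 0.5, size=n))
        lam_log.append(lam)
        lam, _ = boxcox_transform(rng.normal(10.0, 1.0, size=n))
        lam_norm.append(lam)
    return {
        "lambda_lognormal_mean": float(np.mean(lam_log)),
        "lambda_normal_mean": float(np.mean(lam_norm)),
    }


def rgr_exponential_max_error(rate: float = 0.1, n_days: int = 45) -> float:
    """Max |RGR - r| for exact exponential growth over all interval choices."""
    t = np.arange(1, n_days + 1, dtype=float)
    ln_w = np.log(2.0) + rate * t  # W(t) = 2 e^{rt}, replicates identical
    errs = []
    for i in range(n_days - 1):
        for j in range(i + 1, n_days):
            est = traits_mod.compute_rgr(
                [ln_w[i]] * 3, [ln_w[j]] * 3, t[i], t[j]
            )
            errs.append(abs(est - rate))
    return float(np.max(errs))


# ---------------------------------------------------------------------------
# clustering and ideotypes
# ---------------------------------------------------------------------------


def clustering_recovery_ari(
    seed: int, per_group: int = 30, noise_cv: float = 0.02
) -> float:
    """Adjusted Rand index recovering 3 planted temporal growth archetypes."""
    from sklearn.metrics import adjusted_rand_score

    rng = child_rng(seed, "clustering")
    daps = np.arange(12, 57)
    archetypes = [(250.0, 0.12, 30.0), (420.0, 0.18, 27.0), (600.0, 0.25, 24.0)]
    rows, truth = [], []
    for a, (amax, r, t0) in enumerate(archetypes):
        for i in range(per_group):
            curve = amax / (1.0 + np.exp(-r * (daps - t0)))
            curve = curve * (1.0 + noise_cv * rng.standard_normal(len(daps)))
            rows.append(curve)
            truth.append(a)
    idx = [f"A{i:03d}" for i in range(len(rows))]
    prof = pd.DataFrame(rows, index=idx, columns=daps)
    res = profiles.cluster_profiles(prof, k=3, dap_range=(12, 56))
    return float(adjusted_rand_score(truth, res.assignments.loc[idx].to_numpy()))


def ideotype_brute_force_mismatches(seed: int, n_accessions: int = 300) -> int:
    """Symmetric-difference size between select_ideotypes and a brute filter.

    The brute-force path recomputes window-mean percentiles with explicit
    loops and count-based ranks, then applies the top-10%-WUE /
    bottom-5%-ratio definition directly.
    """
    rng = child_rng(seed, "ideotype")
    daps = list(range(15, 32))
    accs = [f"A{i:03d}" for i in range(n_accessions)]
    wue = pd.DataFrame(
        rng.lognormal(0.0, 0.4, size=(n_accessions, len(daps))),
        index=accs, columns=daps,
    )
    ratio = pd.DataFrame(
        rng.lognormal(0.0, 0.4, size=(n_accessions, len(daps))),
        index=accs, columns=daps,
    )
    wue_pct = profiles.percentile_table(wue)
    ratio_pct = profiles.percentile_table(ratio)
    report = profiles.select_ideotypes(wue_pct, ratio_pct, (15, 31))

    # independent brute force: count-based percentile per day, python loops
    def brute_pct(table: pd.DataFrame) -> dict[str, float]:
        out = {a: [] for a in accs}
        n = len(accs)
        for d in daps:
            col = table[d]
            for a in accs:
                less = sum(1 for b in accs if col[b] < col[a])
                equal = sum(1 for b in accs if col[b] == col[a])
                mean_rank = less + (equal + 1) / 2.0  # average rank with ties
                out[a].append(100.0 * (mean_rank - 1.0) / (n - 1.0))
        return {a: sum(v) / len(v) for a, v in out.items()}

    wue_mean = brute_pct(wue)
    ratio_mean = brute_pct(ratio)
    pos = {a for a in accs if wue_mean[a] >= 90.0 and ratio_mean[a] <= 5.0}
    neg = {a for a in accs if wue_mean[a] <= 10.0 and ratio_mean[a] >= 95.0}
    return len(pos ^ set(report.positives)) + len(neg ^ set(report.negatives))


# ---------------------------------------------------------------------------
# candidate-gene window scan oracle
# ---------------------------------------------------------------------------


def candidate_window_mismatches(
    seed: int, n_configs: int = 1000, window: int = 15_000
) -> int:
    """Disagreements between the interval-tree window scan and brute force.

    Each random configuration places one marker and a handful of genes on a
    chromosome; one gene is pinned at exactly `window` bp from the marker and
    one just beyond it, exercising the closed-interval boundary.
    """
    rng = child_rng(seed, "window-scan")
    mismatches = 0
    for c in range(n_configs):
        pos = int(rng.integers(window + 10, 1_000_000))
        genes = []
        for g in range(int(rng.integers(1, 6))):
            start = int(rng.integers(1, 1_000_000))
            end = start + int(rng.integers(100, 40_000))
            genes.append((f"g{g}", start, end))
        # boundary genes: one touching the window edge, one 1 bp outside
        genes.append(("edge_in", pos + window, pos + window + 500))
        if pos - window - 600 > 1:
            genes.append(("edge_out", pos - window - 600, pos - window - 1))
        gdf = pd.DataFrame(
            [
                {"gene_id": f"c{c}_{gid}", "chrom": "Chr1", "start": s, "end": e,
                 "strand": "+"}
                for gid, s, e in genes
            ]
        )
        markers = pd.DataFrame([{"marker": f"m{c}", "chrom": "Chr1", "pos": pos}])
        got = set(scan_window(markers, GeneAnnotation(gdf), window)["gene_id"])
        expected = {
            row.gene_id
            for row in gdf.itertuples()
            if row.start <= pos + window and row.end >= pos - window
        }
        if got != expected:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# MAD outlier filter
# ---------------------------------------------------------------------------


def mad_filter_performance(seed: int) -> dict:
    """Recall / false-removal of the 40-MAD fence on injected 50x outliers.

    ~10,000 top-view cells (252 plants x 40 days) with a 1% injection rate;
    germination jitter and non-germination are switched off so the filter is
    evaluated in isolation on a homogeneous cohort.
    """
    cfg = SimConfig(
        n_accessions=84, n_subpops=3, fst=0.1, n_markers=50, n_chromosomes=2,
        n_replicates=3, n_days=40,
        temperature_phases=[(1, 31, 15.0, 15.0), (32, 36, 24.0, 19.0),
                            (37, 40, 32.0, 22.0)],
        polygenic_h2=0.2, measurement_noise_sd=0.05,
        outlier_rate=0.01, nongerm_rate=0.0, germ_jitter=0,
        amax_cv=0.0, rate_cv=0.0, accession_germ_sd=0.0,
        seed=int(child_rng(seed, "mad").integers(2**31)),
    )
    geno = simulate_genotypes(cfg)
    pheno, _water, truth = simulate_phenotypes(geno, cfg)
    tv = pheno[pheno["trait"] == "tv_px"]
    injected = {
        (p, d) for (p, d, meas) in truth.outliers if meas == "tv_px"
    }
    flagged: set[tuple[str, int]] = set()
    n_cells = 0
    for dap, grp in tv.groupby("DAP"):
        mask = traits_mod.remove_outliers(grp["value"].to_numpy(), k=40.0)
        n_cells += len(grp)
        for pid in grp.loc[mask, "plant_id"]:
            flagged.add((pid, int(dap)))
    clean = n_cells - len(injected)
    recall = 100.0 * len(flagged & injected) / max(len(injected), 1)
    false_removal = 100.0 * len(flagged - injected) / max(clean, 1)
    return {
        "n_cells": n_cells,
        "n_injected": len(injected),
        "recall_pct": recall,
        "false_removal_pct": false_removal,
    }
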