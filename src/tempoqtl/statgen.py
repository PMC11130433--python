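"""Population-genetic and statistical primitives.

Contains the genotype container (with VCF/TSV I/O), minor-allele-frequency
filtering with mean imputation, the Astle-Balding standardized kinship matrix,
genotype principal components, a grid-search Box-Cox transform, and per-day
broad-sense heritability from the one-way random-effects model

    Y_ij = mu + genotype_i + eps_ij,      H^2 = sigma^2_g / (sigma^2_g + sigma^2_e).

Heritability is estimated by the balanced ANOVA method-of-moments estimator
(negative between-group components clipped at zero); a numerical REML fit of
the same model is provided as an independent cross-check path.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "HeritabilityResult",
    "maf_filter_impute",
    "astle_balding_kinship",
    "genotype_pca",
    "boxcox_transform",
    "heritability",
    "heritability_reml",
]


# ---------------------------------------------------------------------------
# genotype container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenotypeMatrix:
    """Accession x marker dosage matrix with marker metadata.

    dosages are 0/1/2 copies of the alternate allele (inbred material uses
    {0, 2} only); missing calls are NaN.  `markers` carries one row per marker
    with columns ``id, chrom, pos, ref, alt, maf``; positions are 1-based bp
    and strictly increasing within a chromosome.  MAF is always recomputed
    from the dosages rather than trusted from input.
    """

    accessions: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray  # (n_accessions, n_markers), float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.markers = self.markers.assign(maf=self.compute_maf())

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def compute_maf(self) -> np.ndarray:
        """Realized minor-allele frequency per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (missing ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_accessions(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accessions.index(a) for a in keep]
        return GenotypeMatrix(list(keep), self.markers.copy(), self.dosages[idx])

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Dosage TSV: marker metadata columns then one column per accession."""
        df = self.markers[["id", "chrom", "pos", "ref", "alt"]].copy()
        for j, acc in enumerate(self.accessions):
            df[acc] = self.dosages[j, :]
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        meta_cols = ["id", "chrom", "pos", "ref", "alt"]
        accessions = [c for c in df.columns if c not in meta_cols]
        markers = df[meta_cols].copy()
        markers["chrom"] = markers["chrom"].astype(str)
        dosages = df[accessions].to_numpy(dtype=float).T
        return cls(accessions, markers, dosages)

    def to_vcf(self, path) -> None:
        """Write a minimal GT-only VCF 4.2 (homozygous calls for dosage 0/2)."""
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=tempoqtl\n")
            for chrom, grp in self.markers.groupby("chrom", sort=False):
                length = int(grp["pos"].max()) + 1000
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.accessions)
                + "\n"
            )
            for i, row in self.markers.iterrows():
                calls = [
                    "./." if np.isnan(d) else gt_code[float(d)]
                    for d in self.dosages[:, i]
                ]
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                    f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic SNPs (GT field) from a VCF via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        accessions = list(vcf.samples)
        rows = []
        dosage_cols = []
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        code = np.array([0.0, 1.0, np.nan, 2.0])
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            rows.append(
                {
                    "id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": var.ALT[0],
                }
            )
            dosage_cols.append(code[var.gt_types])
        vcf.close()
        markers = pd.DataFrame(rows)
        dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(accessions), 0))
        return cls(accessions, markers, dosages)


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix over accessions."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("kinship matrix is not positive semidefinite")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.accessions, columns=self.accessions).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def maf_filter_impute(geno: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop markers with MAF <= maf_min or zero variance; mean-impute missing.

    The keep rule mirrors the study's "MAF > 0.05" cutoff: a marker exactly at
    the threshold is dropped.
    """
    X = geno.dosages
    maf = geno.compute_maf()
    with np.errstate(invalid="ignore"):
        var = np.nanvar(X, axis=0)
    # strict ">" with a float tolerance so a marker exactly at the cutoff
    # (e.g. 1/20 minor alleles) is dropped despite rounding
    keep = np.isfinite(maf) & (maf > maf_min + 1e-9) & (var > 0)
    if not keep.any():
        raise ValueError("all markers removed by MAF/variance filter")
    Xk = X[:, keep].copy()
    col_mean = np.nanmean(Xk, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(Xk))
    Xk[nan_r, nan_c] = col_mean[nan_c]
    markers = geno.markers.loc[keep].reset_index(drop=True)
    return GenotypeMatrix(list(geno.accessions), markers, Xk)


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------


def astle_balding_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Astle-Balding standardized kinship.

    K_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with p_i the observed (post-imputation) alternate-allele frequency.
    Monomorphic markers must be filtered beforehand.
    """
    X = np.asarray(geno.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("kinship requires imputed (complete) dosages")
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker present; run maf_filter_impute first")
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = Z @ Z.T / geno.n_markers
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(geno.accessions), K)


def genotype_pca(geno: GenotypeMatrix, n_pcs: int = 3) -> pd.DataFrame:
    """Top principal-component scores of the column-centered dosage matrix.

    Sign convention: each component's largest-magnitude loading is positive.
    Returns a DataFrame (accessions x PC1..PCn).
    """
    X = np.asarray(geno.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires imputed (complete) dosages")
    if n_pcs >= geno.n_accessions:
        raise ValueError("n_pcs must be smaller than the number of accessions")
    if n_pcs > geno.n_markers:
        raise ValueError("n_pcs cannot exceed the number of markers")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    return pd.DataFrame(
        scores, index=geno.accessions, columns=[f"PC{k + 1}" for k in range(n_pcs)]
    )


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


def boxcox_transform(
    values: np.ndarray,
    lambda_grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
    offset: float | None = None,
) -> tuple[float, np.ndarray]:
    """Box-Cox power transform with profile-likelihood lambda on a grid.

    lambda maximizes the Box-Cox log-likelihood over [lo, hi] at the given
    step; y -> (y^lambda - 1)/lambda, or ln y when lambda == 0.  Values must
    be positive; if `offset` is given it is added first (to lift zeros).
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if offset is not None:
        y = y + offset
    if y.size < 3:
        raise ValueError("need at least 3 values for Box-Cox")
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires positive values (use offset)")
    lo, hi, step = lambda_grid
    grid = np.arange(lo, hi + step / 2, step)
    # vectorized profile log-likelihood over the whole grid:
    # llf(lam) = (lam - 1) sum(ln y) - n/2 ln(var(y^(lam)))
    logy = np.log(y)
    sum_logy = logy.sum()
    n = y.size
    with np.errstate(over="ignore"):
        Yt = np.where(
            np.abs(grid)[:, None] < 1e-12,
            logy[None, :],
            (np.exp(np.outer(grid, logy)) - 1.0) / np.where(np.abs(grid) < 1e-12, 1.0, grid)[:, None],
        )
    var = Yt.var(axis=1)
    llf = (grid - 1.0) * sum_logy - 0.5 * n * np.log(np.where(var > 0, var, np.inf))
    lam = float(grid[np.argmax(llf)])
    if abs(lam) < step / 2:
        lam = 0.0
        transformed = np.log(y)
    else:
        transformed = (y**lam - 1.0) / lam
    return lam, transformed


# ---------------------------------------------------------------------------
# broad-sense heritability
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HeritabilityResult:
    trait: str
    dap: int
    sigma2_genotype: float
    sigma2_error: float
    h2: float
    n_accessions: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("H2 out of [0, 1]")


def _replicate_complete(values: pd.DataFrame, n_replicates: int) -> pd.DataFrame:
    counts = values.notna().sum(axis=1)
    return values.loc[counts >= n_replicates]


def heritability(
    values: pd.DataFrame,
    trait: str = "",
    dap: int = 0,
    n_replicates: int = 3,
) -> HeritabilityResult:
    """Broad-sense heritability at one DAP from replicated accession values.

    `values` is accession x replicate.  Only accessions with the full
    replicate count enter (the study restricted to accessions with three
    germinated replicates).  Balanced one-way ANOVA method of moments:
    sigma2_g = (MSB - MSW) / r clipped at 0, sigma2_e = MSW.
    """
    vals = _replicate_complete(values, n_replicates)
    a = len(vals)
    if a < 2:
        raise ValueError("need at least 2 replicate-complete accessions")
    Y = vals.to_numpy(dtype=float)[:, :n_replicates]
    r = n_replicates
    group_means = Y.mean(axis=1)
    grand = Y.mean()
    msb = r * np.sum((group_means - grand) ** 2) / (a - 1)
    msw = np.sum((Y - group_means[:, None]) ** 2) / (a * (r - 1))
    sigma2_g = max((msb - msw) / r, 0.0)
    sigma2_e = msw
    total = sigma2_g + sigma2_e
    h2 = sigma2_g / total if total > 0 else 0.0
    return HeritabilityResult(trait, dap, sigma2_g, sigma2_e, h2, a)


def heritability_reml(
    values: pd.DataFrame,
    trait: str = "",
    dap: int = 0,
    n_replicates: int = 3,
) -> HeritabilityResult:
    """REML fit of the same one-way random-effects model (numeric path).

    For balanced data with an interior optimum this coincides with the ANOVA
    method-of-moments estimator; kept as an independent cross-check.
    """
    vals = _replicate_complete(values, n_replicates)
    a = len(vals)
    if a < 2:
        raise ValueError("need at least 2 replicate-complete accessions")
    Y = vals.to_numpy(dtype=float)[:, :n_replicates]
    r = n_replicates
    group_means = Y.mean(axis=1)
    grand = Y.mean()
    ssb = r * np.sum((group_means - grand) ** 2)
    ssw = np.sum((Y - group_means[:, None]) ** 2)

    def neg2_reml(params: np.ndarray) -> float:
        log_e, log_g = params
        s2e, s2g = np.exp(log_e), np.exp(log_g)
        lam = s2e + r * s2g  # variance of group totals / r
        return (
            a * (r - 1) * np.log(s2e)
            + (a - 1) * np.log(lam)
            + ssw / s2e
            + ssb / lam
        )

    s2e0 = max(ssw / (a * (r - 1)), 1e-12)
    s2g0 = max((ssb / (a - 1) - s2e0) / r, 1e-12)
    res = optimize.minimize(
        neg2_reml,
        x0=np.log([s2e0, max(s2g0, 1e-8 * s2e0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    s2e, s2g = np.exp(res.x)
    if s2g < 1e-8 * (s2e + s2g):
        s2g = 0.0
    h2 = s2g / (s2g + s2e) if (s2g + s2e) > 0 else 0.0
    return HeritabilityResult(trait, dap, float(s2g), float(s2e), float(h2), a)
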