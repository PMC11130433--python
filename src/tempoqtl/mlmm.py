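"""Multi-locus mixed-model (MLMM) association engine.

Model: y = X beta + u + e with u ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I).
A single eigendecomposition of the kinship matrix K rotates the model to a
diagonal covariance, after which REML over the variance ratio
delta = sigma2_e / sigma2_g is a one-dimensional search (coarse grid on
log delta followed by bounded Brent refinement).  Pseudo-heritability is
sigma2_g / (sigma2_g + sigma2_e) = 1 / (1 + delta).

The stepwise scan adds, at each forward step, the marker with the smallest
generalized-least-squares F-test p-value as a fixed cofactor, re-estimating
variance components between steps (the approximate scan: components are held
fixed while scanning within a step).  The path stops once pseudo-heritability
has effectively reached zero (<= `pseudo_h2_stop`, checked after at least one
addition so the candidate model path is never empty), at `max_steps`, or when
no testable marker remains.  Two models are then selected along the path:

* multiple-Bonferroni (mBonf): the largest model in which every cofactor has
  p <= alpha / m_effective — the stringent tier;
* extended BIC (extBIC): the path model minimizing
  -2 logL_ML + k ln n + 2 gamma ln C(m_effective, k).

The high-confidence set is the union of the two; markers only in the extBIC
model form the lower-confidence tier.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .statgen import KinshipMatrix

__all__ = [
    "MixedLMM",
    "MLMMResults",
    "VarComp",
    "ScanResult",
    "reml_variance_components",
    "scan_markers",
    "select_models",
    "kinship_eigendecomposition",
]

_LOG_DELTA_RANGE = (np.log(1e-5), np.log(1e5))
_GRID_POINTS = 64


@dataclasses.dataclass
class VarComp:
    sigma2_g: float
    sigma2_e: float
    pseudo_h2: float
    delta: float
    loglik_reml: float


@dataclasses.dataclass
class ScanResult:
    """Per-marker GLS association results under one cofactor set."""

    marker_ids: np.ndarray
    effects: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    collinear: np.ndarray  # flagged markers, p reported as 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.marker_ids,
                "effect": self.effects,
                "se": self.se,
                "p": self.pvalues,
                "collinear": self.collinear,
            }
        )


@dataclasses.dataclass
class StepRecord:
    """State of the forward path after k cofactor additions."""

    cofactors: tuple[str, ...]
    varcomp: VarComp
    cofactor_pvalues: dict[str, float]
    loglik_ml: float
    scan: ScanResult | None  # scan performed *from* this model


def kinship_eigendecomposition(K: KinshipMatrix | np.ndarray):
    """Eigendecomposition of K with eigenvalues clipped to be nonnegative."""
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    w, U = np.linalg.eigh(Kv)
    return np.clip(w, 0.0, None), U


def _gls_profile(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray, delta: float):
    """Weighted LS pieces at a given delta in the rotated model.

    Returns (rss, logdet_v, logdet_xwx, beta, XtWX_inv) with weights
    w_i = 1 / (d_i + delta).
    """
    v = d + delta
    w = 1.0 / v
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    try:
        c = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("rank-deficient fixed-effect design") from exc
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid**2))
    logdet_v = float(np.sum(np.log(v)))
    logdet_xwx = float(2.0 * np.sum(np.log(np.diag(c))))
    return rss, logdet_v, logdet_xwx, beta, XtWX


def _reml_loglik(yr, Xr, d, delta) -> float:
    n, q = Xr.shape
    rss, logdet_v, logdet_xwx, _, _ = _gls_profile(yr, Xr, d, delta)
    nq = n - q
    sign, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi))
        - nq
        - nq * np.log(rss)
        - logdet_v
        - logdet_xwx
        + logdet_xx
    )


def _ml_loglik(yr, Xr, d, delta) -> float:
    n = len(yr)
    rss, logdet_v, _, _, _ = _gls_profile(yr, Xr, d, delta)
    return 0.5 * (n * np.log(n / (2 * np.pi)) - n - n * np.log(rss) - logdet_v)


def _optimize_delta(fun) -> float:
    """Maximize a 1-D likelihood over log delta: coarse grid + Brent refine."""
    lo, hi = _LOG_DELTA_RANGE
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([fun(g) for g in grid])
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        lambda t: -fun(t), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if -res.fun >= vals[i] else grid[i]
    return float(np.exp(best))


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray | None = None,
    k_eig=None,
) -> VarComp:
    """REML variance components of the kinship mixed model.

    Either `K` or a precomputed `k_eig = (eigenvalues, eigenvectors)` must be
    given.  X must be full column rank (an informative error names the
    offending columns otherwise).
    """
    if k_eig is None:
        if K is None:
            raise ValueError("provide K or k_eig")
        k_eig = kinship_eigendecomposition(K)
    d, U = k_eig
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_rank(X)
    yr = U.T @ y
    Xr = U.T @ X
    delta = _optimize_delta(lambda t: _reml_loglik(yr, Xr, d, np.exp(t)))
    ll = _reml_loglik(yr, Xr, d, delta)
    rss, *_ = _gls_profile(yr, Xr, d, delta)
    n, q = X.shape
    sigma2_g = rss / (n - q)
    sigma2_e = delta * sigma2_g
    return VarComp(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        pseudo_h2=float(1.0 / (1.0 + delta)),
        delta=float(delta),
        loglik_reml=float(ll),
    )


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity
        _, r = np.linalg.qr(X)
        bad = [j for j in range(X.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise ValueError(f"rank-deficient design matrix (columns {bad})")


def _scan_rotated(
    yr: np.ndarray,
    Xr: np.ndarray,
    Gr: np.ndarray,
    d: np.ndarray,
    delta: float,
):
    """Vectorized GLS F-tests (1 df) of each marker added to [X, g].

    Variance components fixed at `delta` (approximate scan).  Returns
    (effects, se, pvalues, collinear_mask).
    """
    n, q = Xr.shape
    w = 1.0 / (d + delta)
    sw = np.sqrt(w)
    yt = sw * yr
    Xt = sw[:, None] * Xr
    Gt = sw[:, None] * Gr
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)
    RG = Gt - Q @ (Q.T @ Gt)
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    rss0 = float(ry @ ry)
    tol = 1e-10 * max(1.0, float(np.max(gg, initial=0.0)))
    collinear = gg <= tol
    gg_safe = np.where(collinear, 1.0, gg)
    beta = gy / gg_safe
    rss1 = rss0 - beta * gy
    df = n - q - 1
    rss1 = np.clip(rss1, 1e-300, None)
    fstat = (rss0 - rss1) / (rss1 / df)
    pvals = stats.f.sf(fstat, 1, df)
    se = np.sqrt(rss1 / df / gg_safe)
    pvals = np.where(collinear, 1.0, pvals)
    beta = np.where(collinear, 0.0, beta)
    se = np.where(collinear, np.inf, se)
    return beta, se, pvals, collinear


def scan_markers(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    varcomp: VarComp,
    markers: np.ndarray,
    marker_ids: Sequence[str] | None = None,
    exact: bool = False,
) -> ScanResult:
    """GLS association scan of candidate markers under fixed cofactors.

    With `exact=True`, variance components are re-estimated per marker
    (slow path, for oracle checks); otherwise they stay at `varcomp`.
    """
    d, U = kinship_eigendecomposition(K)
    yr, Xr = U.T @ np.asarray(y, float), U.T @ np.atleast_2d(np.asarray(X, float))
    Gr = U.T @ np.asarray(markers, float)
    if marker_ids is None:
        marker_ids = np.array([f"m{j}" for j in range(Gr.shape[1])])
    if exact:
        effects, ses, ps, coll = [], [], [], []
        for j in range(Gr.shape[1]):
            Xj = np.column_stack([Xr, Gr[:, j]])
            try:
                delta_j = _optimize_delta(
                    lambda t: _reml_loglik(yr, Xj, d, np.exp(t))
                )
            except np.linalg.LinAlgError:
                effects.append(0.0), ses.append(np.inf), ps.append(1.0), coll.append(True)
                continue
            b, s, p, c = _scan_rotated(yr, Xr, Gr[:, [j]], d, delta_j)
            effects.append(b[0]), ses.append(s[0]), ps.append(p[0]), coll.append(c[0])
        return ScanResult(
            np.asarray(marker_ids), np.array(effects), np.array(ses),
            np.array(ps), np.array(coll),
        )
    beta, se, pvals, collinear = _scan_rotated(yr, Xr, Gr, d, varcomp.delta)
    return ScanResult(np.asarray(marker_ids), beta, se, pvals, collinear)


def _cofactor_pvalues(yr, Xr0, Gr_cof, d, delta) -> np.ndarray:
    """Drop-one GLS t-test p-value of each cofactor within the full model."""
    k = Gr_cof.shape[1]
    if k == 0:
        return np.empty(0)
    X_full = np.column_stack([Xr0, Gr_cof])
    n, q = X_full.shape
    w = 1.0 / (d + delta)
    Xw = X_full * w[:, None]
    XtWX = X_full.T @ Xw
    XtWy = Xw.T @ yr
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ XtWy
    resid = yr - X_full @ beta
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / (n - q)
    se = np.sqrt(sigma2 * np.diag(XtWX_inv))
    tstat = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), n - q)
    return pv[-k:]


def select_models(
    steps: list[StepRecord],
    m_effective: int,
    n_obs: int,
    alpha: float = 0.05,
    gamma: float = 1.0,
):
    """mBonf / extBIC model choice along a recorded forward path.

    Returns (mbonf_index, extbic_index, tiers) where tiers maps marker id ->
    'stringent' (in the mBonf model) or 'lower' (extBIC model only).
    """
    threshold = alpha / max(m_effective, 1)
    mbonf_idx = 0
    for k, step in enumerate(steps):
        ps = list(step.cofactor_pvalues.values())
        if ps and all(p <= threshold for p in ps):
            mbonf_idx = k
    log_choose = [
        special.gammaln(m_effective + 1)
        - special.gammaln(k + 1)
        - special.gammaln(m_effective - k + 1)
        for k in range(len(steps))
    ]
    ebic = [
        -2.0 * step.loglik_ml
        + len(step.cofactors) * np.log(n_obs)
        + 2.0 * gamma * log_choose[k]
        for k, step in enumerate(steps)
    ]
    extbic_idx = int(np.argmin(ebic)) if ebic else 0
    mbonf_set = set(steps[mbonf_idx].cofactors) if steps else set()
    extbic_set = set(steps[extbic_idx].cofactors) if steps else set()
    tiers = {mid: "stringent" for mid in mbonf_set}
    for mid in extbic_set - mbonf_set:
        tiers[mid] = "lower"
    return mbonf_idx, extbic_idx, tiers


class MixedLMM:
    """Stepwise multi-locus mixed model for one trait at one time point.

    Parameters
    ----------
    y : phenotype vector over accessions (complete cases only).
    X : fixed covariates including the intercept (typically intercept + the
        first three genotype principal components).
    K : kinship matrix (or pass a reusable `k_eig` eigendecomposition).
    markers : accession x marker dosage matrix (filtered, imputed).
    marker_meta : DataFrame with columns (id, chrom, pos) aligned to
        `markers`; candidate order (and p-value tie-breaks) follow
        (chrom, pos).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        K: KinshipMatrix | np.ndarray | None,
        markers: np.ndarray,
        marker_meta: pd.DataFrame | None = None,
        k_eig=None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("y must be complete (drop missing cases first)")
        _check_rank(self.X)
        if k_eig is None:
            if K is None:
                raise ValueError("provide K or k_eig")
            k_eig = kinship_eigendecomposition(K)
        self.d, self.U = k_eig
        G = np.asarray(markers, dtype=float)
        if marker_meta is None:
            marker_meta = pd.DataFrame(
                {
                    "id": [f"m{j}" for j in range(G.shape[1])],
                    "chrom": "0",
                    "pos": np.arange(G.shape[1]),
                }
            )
        order = np.lexsort(
            (marker_meta["pos"].to_numpy(), marker_meta["chrom"].to_numpy())
        )
        self.meta = marker_meta.iloc[order].reset_index(drop=True)
        self.G = G[:, order]
        # rotate once
        self.yr = self.U.T @ self.y
        self.Xr = self.U.T @ self.X
        self.Gr = self.U.T @ self.G

    @property
    def n_markers(self) -> int:
        return self.G.shape[1]

    def fit(
        self,
        max_steps: int = 20,
        pseudo_h2_stop: float = 0.01,
        alpha: float = 0.05,
        gamma: float = 1.0,
        m_effective: int | None = None,
    ) -> "MLMMResults":
        """Run the forward path and select the mBonf / extBIC models."""
        n = len(self.y)
        m_eff = m_effective if m_effective is not None else self.n_markers
        cof: list[int] = []
        available = np.ones(self.n_markers, dtype=bool)
        steps: list[StepRecord] = []
        while True:
            Xcur = (
                np.column_stack([self.Xr, self.Gr[:, cof]]) if cof else self.Xr
            )
            delta = _optimize_delta(
                lambda t: _reml_loglik(self.yr, Xcur, self.d, np.exp(t))
            )
            ll_reml = _reml_loglik(self.yr, Xcur, self.d, delta)
            rss, *_ = _gls_profile(self.yr, Xcur, self.d, delta)
            q = Xcur.shape[1]
            s2g = rss / (n - q)
            vc = VarComp(
                sigma2_g=float(s2g),
                sigma2_e=float(delta * s2g),
                pseudo_h2=float(1.0 / (1.0 + delta)),
                delta=float(delta),
                loglik_reml=float(ll_reml),
            )
            delta_ml = _optimize_delta(
                lambda t: _ml_loglik(self.yr, Xcur, self.d, np.exp(t))
            )
            ll_ml = _ml_loglik(self.yr, Xcur, self.d, delta_ml)
            cof_p = _cofactor_pvalues(
                self.yr, self.Xr, self.Gr[:, cof], self.d, delta
            )
            ids = tuple(self.meta["id"].iloc[j] for j in cof)
            scan_res = None
            stop = (
                len(cof) >= max_steps
                or (len(cof) >= 1 and vc.pseudo_h2 <= pseudo_h2_stop)
                or not available.any()
            )
            if not stop:
                cand = np.nonzero(available)[0]
                beta, se, pv, coll = _scan_rotated(
                    self.yr, Xcur, self.Gr[:, cand], self.d, delta
                )
                full_p = np.full(self.n_markers, np.nan)
                full_p[cand] = pv
                scan_res = ScanResult(
                    self.meta["id"].to_numpy()[cand], beta, se, pv, coll
                )
                if np.all(coll):
                    stop = True
                else:
                    best_local = int(np.argmin(pv))  # stable: (chrom,pos) order
                    best = int(cand[best_local])
            steps.append(
                StepRecord(ids, vc, dict(zip(ids, cof_p)), float(ll_ml), scan_res)
            )
            if stop:
                break
            cof.append(best)
            available[best] = False
        mbonf_idx, extbic_idx, tiers = select_models(
            steps, m_eff, n, alpha=alpha, gamma=gamma
        )
        return MLMMResults(self, steps, mbonf_idx, extbic_idx, tiers, m_eff, alpha, gamma)


class MLMMResults:
    """Results of a stepwise MLMM fit.

    Attributes
    ----------
    steps : the forward path; steps[k] is the model with k cofactors.
    mbonf / extbic : marker-id sets of the two selected models.
    high_confidence : their union; `tiers` maps id -> stringent / lower.
    """

    def __init__(self, model, steps, mbonf_idx, extbic_idx, tiers, m_eff, alpha, gamma):
        self.model = model
        self.steps = steps
        self.mbonf_index = mbonf_idx
        self.extbic_index = extbic_idx
        self.tiers = tiers
        self.m_effective = m_eff
        self.alpha = alpha
        self.gamma = gamma

    @property
    def cofactors(self) -> tuple[str, ...]:
        return self.steps[-1].cofactors

    @property
    def mbonf(self) -> set[str]:
        return set(self.steps[self.mbonf_index].cofactors)

    @property
    def extbic(self) -> set[str]:
        return set(self.steps[self.extbic_index].cofactors)

    @property
    def high_confidence(self) -> set[str]:
        return self.mbonf | self.extbic

    @property
    def pseudo_h2_path(self) -> np.ndarray:
        return np.array([s.varcomp.pseudo_h2 for s in self.steps])

    @property
    def null_scan(self) -> ScanResult | None:
        """Single-marker scan from the no-cofactor model (Manhattan input)."""
        return self.steps[0].scan

    def summary(self) -> str:
        vc0 = self.steps[0].varcomp
        lines = [
            "Multi-locus mixed model (stepwise forward)",
            "=" * 46,
            f"observations:        {len(self.model.y)}",
            f"markers tested:      {self.model.n_markers}",
            f"null pseudo-h2:      {vc0.pseudo_h2:.4f}",
            f"forward path length: {len(self.steps) - 1}",
            f"mBonf threshold:     {self.alpha / max(self.m_effective, 1):.3e}",
            f"mBonf model size:    {self.mbonf_index}",
            f"extBIC model size:   {self.extbic_index}",
            "",
            "cofactor             step  p(final model)  tier",
            "-" * 46,
        ]
        final = self.steps[-1]
        for k, mid in enumerate(final.cofactors, start=1):
            tier = self.tiers.get(mid, "-")
            p = final.cofactor_pvalues.get(mid, np.nan)
            lines.append(f"{mid:<20} {k:>4}  {p:>14.3e}  {tier}")
        return "\n".join(lines)

    def hits_frame(self, trait: str = "", dap: int = 0) -> pd.DataFrame:
        """High-confidence markers as rows (marker, trait, DAP, tier, p)."""
        final = self.steps[-1]
        rows = []
        for mid in sorted(self.high_confidence):
            rows.append(
                {
                    "marker": mid,
                    "trait": trait,
                    "DAP": dap,
                    "tier": self.tiers[mid],
                    "p": final.cofactor_pvalues.get(mid, np.nan),
                }
            )
        return pd.DataFrame(rows, columns=["marker", "trait", "DAP", "tier", "p"])
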