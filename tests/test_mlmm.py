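"""Mixed-model engine: REML variance components, GLS scan against a
brute-force oracle, the forward path, and mBonf/extBIC model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempoqtl.mlmm import (
    MixedLMM,
    StepRecord,
    VarComp,
    kinship_eigendecomposition,
    reml_variance_components,
    scan_markers,
    select_models,
)
from tempoqtl.statgen import astle_balding_kinship, genotype_pca
from tempoqtl.validation import _gls_pvalues_explicit, pick_marker_near_maf


@pytest.fixture(scope="module")
def kinship_setup(filtered_geno):
    K = astle_balding_kinship(filtered_geno)
    pcs = genotype_pca(filtered_geno, 3).to_numpy()
    X = np.column_stack([np.ones(filtered_geno.n_accessions), pcs])
    return filtered_geno, K, X, kinship_eigendecomposition(K)


def _structured_y(K_eig, h2, rng, n):
    d, U = K_eig
    g = U @ (np.sqrt(d) * rng.standard_normal(n))
    g = g / g.std()
    e = rng.standard_normal(n)
    return np.sqrt(h2) * g + np.sqrt(1 - h2) * e


class TestReml:
    def test_recovers_planted_pseudo_h2(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        n = geno.n_accessions
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(100):
            y = _structured_y(k_eig, 0.5, rng, n)
            ests.append(reml_variance_components(y, X, k_eig=k_eig).pseudo_h2)
        # small panel: generous but centered recovery band
        assert np.mean(ests) == pytest.approx(0.5, abs=0.12)

    def test_noise_has_low_pseudo_h2(self):
        """Pure iid phenotypes yield pseudo-h2 < 0.1 in >= 95% of runs
        (panel large enough for the boundary estimator to concentrate)."""
        from tempoqtl.validation import _structured_genotypes

        n = 300
        geno = _structured_genotypes(99, n, 300, "null-h2")
        k_eig = kinship_eigendecomposition(astle_balding_kinship(geno))
        X = np.column_stack([np.ones(n), genotype_pca(geno, 3).to_numpy()])
        rng = np.random.default_rng(6)
        low = 0
        n_runs = 200
        for _ in range(n_runs):
            vc = reml_variance_components(
                rng.standard_normal(n), X, k_eig=k_eig
            )
            low += vc.pseudo_h2 < 0.1
        assert low / n_runs >= 0.95

    def test_identity_kinship_recovers_total_variance(self):
        rng = np.random.default_rng(7)
        n = 200
        y = rng.normal(0, 2.0, n)
        X = np.ones((n, 1))
        vc = reml_variance_components(y, X, K=np.eye(n))
        total = vc.sigma2_g + vc.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_rank_deficient_design_reported(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        Xbad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank-deficient"):
            reml_variance_components(
                np.random.default_rng(0).standard_normal(geno.n_accessions),
                Xbad, k_eig=k_eig,
            )


class TestScan:
    def test_identity_kinship_matches_plain_ols(self):
        rng = np.random.default_rng(8)
        n, m = 80, 40
        G = rng.choice([0.0, 2.0], size=(n, m))
        G[:, 0] = np.repeat([0.0, 2.0], n // 2)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        vc = VarComp(1.0, 1.0, 0.5, 1.0, 0.0)
        res = scan_markers(y, X, np.eye(n), vc, G)
        for j in range(m):
            if res.collinear[j]:
                continue
            slope, inter, r, p, se = stats.linregress(G[:, j], y)
            assert res.pvalues[j] == pytest.approx(p, abs=1e-8)

    def test_matches_explicit_inverse_oracle(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(9)
        y = _structured_y(k_eig, 0.4, rng, geno.n_accessions)
        vc = reml_variance_components(y, X, k_eig=k_eig)
        res = scan_markers(y, X, K, vc, geno.dosages)
        oracle = _gls_pvalues_explicit(
            y, X, K.values, vc.sigma2_g, vc.sigma2_e, geno.dosages
        )
        assert np.max(np.abs(res.pvalues - oracle)) < 1e-8

    def test_exact_scan_close_to_approximate_on_null(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(10)
        y = rng.standard_normal(geno.n_accessions)
        vc = reml_variance_components(y, X, k_eig=k_eig)
        approx = scan_markers(y, X, K, vc, geno.dosages[:, :20])
        exact = scan_markers(y, X, K, vc, geno.dosages[:, :20], exact=True)
        # same ordering of evidence even if the variance ratio is refit
        assert stats.spearmanr(approx.pvalues, exact.pvalues).statistic > 0.99

    def test_planted_marker_has_smallest_p(self):
        """A marker explaining ~25% of variance tops the scan in >=95% of
        simulations."""
        from tempoqtl.validation import _structured_genotypes

        wins, n_runs = 0, 100
        for run in range(n_runs):
            geno = _structured_genotypes(123 + run, 100, 300, "scan-power")
            j = pick_marker_near_maf(geno, 0.4)
            g = geno.dosages[:, j]
            rng = np.random.default_rng(1000 + run)
            beta = np.sqrt(0.25 / 0.75 / np.var(g))
            y = beta * g + rng.standard_normal(len(g))
            K = astle_balding_kinship(geno)
            X = np.ones((len(g), 1))
            vc = reml_variance_components(y, X, K)
            res = scan_markers(y, X, K, vc, geno.dosages)
            if np.argmin(res.pvalues) == j:
                wins += 1
        assert wins / n_runs >= 0.95

    def test_location_scale_invariance(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(11)
        y = _structured_y(k_eig, 0.4, rng, geno.n_accessions)
        vc = reml_variance_components(y, X, k_eig=k_eig)
        res1 = scan_markers(y, X, K, vc, geno.dosages)
        y2 = 3.0 * y + 10.0
        vc2 = reml_variance_components(y2, X, k_eig=k_eig)
        res2 = scan_markers(y2, X, K, vc2, geno.dosages)
        assert np.allclose(res1.pvalues, res2.pvalues, atol=1e-8)

    def test_collinear_marker_flagged(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(12)
        y = rng.standard_normal(geno.n_accessions)
        vc = reml_variance_components(y, X, k_eig=k_eig)
        G = np.column_stack([np.full(geno.n_accessions, 2.0), geno.dosages[:, 0]])
        res = scan_markers(y, X, K, vc, G)
        assert res.collinear[0]
        assert res.pvalues[0] == 1.0


class TestForwardPath:
    def test_strong_marker_is_first_cofactor(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        j = pick_marker_near_maf(geno, 0.4)
        rng = np.random.default_rng(13)
        g = geno.dosages[:, j]
        y = 1.5 * g + rng.standard_normal(len(g))
        model = MixedLMM(y, X, None, geno.dosages,
                         geno.markers[["id", "chrom", "pos"]], k_eig=k_eig)
        res = model.fit()
        assert res.cofactors[0] == geno.markers["id"].iloc[j]

    def test_null_path_terminates(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(14)
        y = rng.standard_normal(geno.n_accessions)
        model = MixedLMM(y, X, None, geno.dosages,
                         geno.markers[["id", "chrom", "pos"]], k_eig=k_eig)
        res = model.fit(max_steps=20)
        assert len(res.steps) - 1 <= 20
        # stopping reason: pseudo-heritability exhausted or step cap
        assert (res.steps[-1].varcomp.pseudo_h2 <= 0.01
                or len(res.steps) - 1 == 20)

    def test_pseudo_h2_nonincreasing_along_path(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(15)
        j = pick_marker_near_maf(geno, 0.4)
        y = (geno.dosages[:, j] + 0.8 * geno.dosages[:, 5]
             + _structured_y(k_eig, 0.4, rng, geno.n_accessions))
        model = MixedLMM(y, X, None, geno.dosages,
                         geno.markers[["id", "chrom", "pos"]], k_eig=k_eig)
        res = model.fit()
        path = res.pseudo_h2_path
        assert np.all(np.diff(path) <= 0.02)

    def test_marker_order_irrelevant(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(16)
        j = pick_marker_near_maf(geno, 0.4)
        y = geno.dosages[:, j] + rng.standard_normal(geno.n_accessions)
        meta = geno.markers[["id", "chrom", "pos"]]
        res1 = MixedLMM(y, X, None, geno.dosages, meta, k_eig=k_eig).fit()
        perm = rng.permutation(geno.n_markers)
        res2 = MixedLMM(y, X, None, geno.dosages[:, perm],
                        meta.iloc[perm].reset_index(drop=True), k_eig=k_eig).fit()
        assert res1.cofactors == res2.cofactors
        assert res1.mbonf == res2.mbonf

    def test_selected_models_are_path_subsets(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(17)
        j = pick_marker_near_maf(geno, 0.4)
        y = 1.2 * geno.dosages[:, j] + rng.standard_normal(geno.n_accessions)
        res = MixedLMM(y, X, None, geno.dosages,
                       geno.markers[["id", "chrom", "pos"]], k_eig=k_eig).fit()
        path = set(res.cofactors)
        assert res.mbonf <= path
        assert res.extbic <= path
        assert res.high_confidence == res.mbonf | res.extbic

    def test_summary_renders(self, kinship_setup):
        geno, K, X, k_eig = kinship_setup
        rng = np.random.default_rng(18)
        y = rng.standard_normal(geno.n_accessions)
        res = MixedLMM(y, X, None, geno.dosages,
                       geno.markers[["id", "chrom", "pos"]], k_eig=k_eig).fit()
        text = res.summary()
        assert "Multi-locus mixed model" in text
        assert "pseudo-h2" in text


class TestSelectModels:
    def _steps(self, cof_pvalues_by_model, lls):
        steps = []
        for k, pvals in enumerate(cof_pvalues_by_model):
            ids = tuple(f"c{i}" for i in range(k))
            steps.append(
                StepRecord(
                    cofactors=ids,
                    varcomp=VarComp(1.0, 1.0, 0.5, 1.0, 0.0),
                    cofactor_pvalues=dict(zip(ids, pvals)),
                    loglik_ml=lls[k],
                    scan=None,
                )
            )
        return steps

    def test_bonferroni_threshold_arithmetic(self):
        # one cofactor at p=1e-10 with m=1000, alpha=0.05 -> inside mBonf
        steps = self._steps([[], [1e-10]], [0.0, 5.0])
        mb, _, tiers = select_models(steps, 1000, 100, alpha=0.05)
        assert mb == 1
        assert tiers["c0"] == "stringent"
        # p = 1e-3 > 5e-5 -> excluded
        steps = self._steps([[], [1e-3]], [0.0, 5.0])
        mb, _, tiers = select_models(steps, 1000, 100, alpha=0.05)
        assert mb == 0

    def test_extbic_only_marker_gets_lower_tier(self):
        # big ML gain so extBIC prefers the 1-cofactor model, p too weak for mBonf
        steps = self._steps([[], [1e-3]], [0.0, 50.0])
        mb, eb, tiers = select_models(steps, 1000, 100, alpha=0.05)
        assert mb == 0 and eb == 1
        assert tiers["c0"] == "lower"

    def test_empty_path_selects_null_model(self):
        steps = self._steps([[]], [0.0])
        mb, eb, tiers = select_models(steps, 100, 50)
        assert mb == eb == 0
        assert tiers == {}
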