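"""Statistical-genetics primitives: MAF filter + imputation, Astle-Balding
kinship, genotype PCA, Box-Cox and broad-sense heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempoqtl import statgen
from tempoqtl.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def _geno(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": "Chr01",
            "pos": positions or list(range(1, m + 1)),
            "ref": "A",
            "alt": "T",
        }
    )
    return statgen.GenotypeMatrix([f"A{i}" for i in range(n)], markers, dosages)


class TestMafFilter:
    def test_monomorphic_dropped(self):
        g = _geno(np.column_stack([np.full(10, 2.0), [0, 2] * 5]))
        out = statgen.maf_filter_impute(g)
        assert list(out.markers["id"]) == ["m1"]

    def test_boundary_maf_dropped_under_strict_rule(self):
        """One dosage-0 accession among 20 gives MAF exactly 2/40 = 0.05;
        the 'keep MAF > 0.05' rule drops it."""
        col = np.full(20, 2.0)
        col[0] = 0.0
        keeper = np.array([0, 2] * 10, dtype=float)
        g = _geno(np.column_stack([col, keeper]))
        out = statgen.maf_filter_impute(g, maf_min=0.05)
        assert list(out.markers["id"]) == ["m1"]

    def test_missing_imputed_with_marker_mean(self):
        col = np.array([0.0, 2, 2, 2, np.nan])
        g = _geno(np.column_stack([col, [0, 2, 0, 2, 0]]))
        out = statgen.maf_filter_impute(g, maf_min=0.01)
        j = list(out.markers["id"]).index("m0")
        assert out.dosages[4, j] == pytest.approx(1.5)

    def test_all_markers_dropped_is_error(self):
        g = _geno(np.full((6, 2), 2.0))
        with pytest.raises(ValueError):
            statgen.maf_filter_impute(g)


class TestKinship:
    def test_two_accession_formula(self):
        g = _geno([[2.0], [0.0]])
        K = statgen.astle_balding_kinship(g)
        assert np.allclose(K.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_permutation_equivariance(self, filtered_geno):
        K = statgen.astle_balding_kinship(filtered_geno).values
        perm = np.random.default_rng(1).permutation(filtered_geno.n_accessions)
        gp = statgen.GenotypeMatrix(
            [filtered_geno.accessions[i] for i in perm],
            filtered_geno.markers.copy(),
            filtered_geno.dosages[perm],
        )
        Kp = statgen.astle_balding_kinship(gp).values
        assert np.allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)

    def test_matches_per_entry_loop_oracle(self, filtered_geno):
        K = statgen.astle_balding_kinship(filtered_geno).values
        X = filtered_geno.dosages
        p = X.mean(axis=0) / 2
        n, m = X.shape
        expected = np.zeros((n, n))
        for j in range(n):
            for k in range(j, n):
                acc = 0.0
                for i in range(m):
                    acc += (X[j, i] - 2 * p[i]) * (X[k, i] - 2 * p[i]) / (
                        2 * p[i] * (1 - p[i])
                    )
                expected[j, k] = expected[k, j] = acc / m
        assert np.allclose(K, expected, atol=1e-10)

    def test_inbred_diagonal_near_two(self, filtered_geno):
        K = statgen.astle_balding_kinship(filtered_geno).values
        assert np.mean(np.diag(K)) == pytest.approx(2.0, abs=0.2)

    def test_allele_flip_invariance(self, filtered_geno):
        K = statgen.astle_balding_kinship(filtered_geno).values
        flipped = filtered_geno.dosages.copy()
        flipped[:, ::2] = 2.0 - flipped[:, ::2]
        gf = statgen.GenotypeMatrix(
            list(filtered_geno.accessions), filtered_geno.markers.copy(), flipped
        )
        Kf = statgen.astle_balding_kinship(gf).values
        assert np.allclose(Kf, K, atol=1e-10)

    def test_monomorphic_marker_is_error(self):
        g = _geno(np.column_stack([[2.0, 2.0, 2.0], [0.0, 2.0, 0.0]]))
        with pytest.raises(ValueError):
            statgen.astle_balding_kinship(g)


class TestPca:
    def test_scores_orthogonal(self, filtered_geno):
        s = statgen.genotype_pca(filtered_geno, 3).to_numpy()
        off = s.T @ s - np.diag(np.diag(s.T @ s))
        assert np.max(np.abs(off)) < 1e-8 * np.abs(s).max() ** 2

    def test_all_pcs_capture_full_variance(self):
        """With n-1 components the score matrix carries the entire centered
        dosage variance (the decomposition is lossless)."""
        rng = np.random.default_rng(0)
        X = rng.choice([0.0, 2.0], size=(12, 8))
        X[:, 0] = [0, 2] * 6  # ensure polymorphic
        g = _geno(X)
        scores = statgen.genotype_pca(g, 8).to_numpy()
        Xc = X - X.mean(axis=0)
        assert np.sum(scores**2) == pytest.approx(np.sum(Xc**2), abs=1e-8)

    def test_too_many_pcs_rejected(self, filtered_geno):
        with pytest.raises(ValueError):
            statgen.genotype_pca(filtered_geno, filtered_geno.n_accessions)


class TestBoxCox:
    def test_zero_lambda_branch_is_log(self, rng):
        y = rng.lognormal(0, 0.5, 400)
        lam, t = statgen.boxcox_transform(y)
        if lam == 0.0:
            assert np.allclose(t, np.log(y))
        # direct check of the branch regardless of the estimate
        lam2, t2 = statgen.boxcox_transform(np.exp(rng.normal(0, 1, 500)))
        assert abs(lam2) <= 0.15

    def test_grid_matches_scipy_profile_llf(self, rng):
        y = rng.gamma(4.0, 2.0, 300)
        lam, _ = statgen.boxcox_transform(y)
        grid = np.arange(-2, 2.005, 0.01)
        llf = [stats.boxcox_llf(l, y) for l in grid]
        assert lam == pytest.approx(grid[int(np.argmax(llf))], abs=1e-9)

    def test_normal_sample_near_identity(self, rng):
        """lambda is weakly identified for a single low-CV normal sample;
        the average over replicates sits near the identity transform."""
        lams = [
            statgen.boxcox_transform(rng.normal(10.0, 1.0, 500))[0]
            for _ in range(20)
        ]
        assert abs(np.mean(lams) - 1.0) <= 0.25

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            statgen.boxcox_transform(np.array([1.0, 0.0, 2.0]))


class TestHeritability:
    def test_pure_genetic_signal_gives_one(self):
        vals = pd.DataFrame(
            {0: [1.0, 2.0, 3.0], 1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0]},
            index=["a", "b", "c"],
        )
        assert statgen.heritability(vals).h2 == pytest.approx(1.0)

    def test_iid_noise_has_near_zero_mean(self, rng):
        ests = []
        for _ in range(200):
            y = rng.standard_normal((200, 3))
            ests.append(statgen.heritability(pd.DataFrame(y)).h2)
        assert np.mean(ests) < 0.05

    def test_reml_equals_anova_on_balanced_data(self, rng):
        for _ in range(5):
            g = rng.normal(0, 1.0, 50)
            y = g[:, None] + rng.normal(0, 0.8, (50, 3))
            df = pd.DataFrame(y)
            mom = statgen.heritability(df)
            reml = statgen.heritability_reml(df)
            assert reml.h2 == pytest.approx(mom.h2, abs=1e-6)

    def test_replicate_incomplete_accessions_excluded(self):
        vals = pd.DataFrame(
            {0: [1.0, 2.0, 3.0], 1: [1.1, 2.1, np.nan], 2: [0.9, 1.9, np.nan]},
            index=["a", "b", "c"],
        )
        res = statgen.heritability(vals)
        assert res.n_accessions == 2

    def test_too_few_accessions_rejected(self):
        with pytest.raises(ValueError):
            statgen.heritability(pd.DataFrame([[1.0, 1.0, 1.0]]))


class TestHeritabilityOverTime:
    def _h2_curve(self, cfg):
        geno = simulate_genotypes(cfg)
        pheno, _, _ = simulate_phenotypes(geno, cfg)
        wide = pheno.pivot_table(
            index=["plant_id", "accession", "replicate", "DAP"],
            columns="trait", values="value", aggfunc="first",
        ).reset_index()
        wide["area"] = wide["tv_px"] + wide["sv1_px"] + wide["sv2_px"]
        curve = {}
        for dap, grp in wide.groupby("DAP"):
            vals = grp.pivot_table(index="accession", columns="replicate",
                                   values="area")
            curve[dap] = statgen.heritability(vals).h2
        return pd.Series(curve)

    def test_realized_ratio_matches_configured_target(self):
        """With pure CV noise and no other plant-level variation the
        between:within ratio hits the configured polygenic target."""
        cfg = SimConfig(
            n_accessions=150, n_markers=60, n_days=30,
            temperature_phases=[(1, 18, 15.0, 15.0), (19, 24, 24.0, 19.0),
                                (25, 30, 32.0, 22.0)],
            polygenic_h2=0.4, measurement_noise_sd=0.05,
            nongerm_rate=0.0, germ_jitter=0, amax_cv=0.0, rate_cv=0.0,
            accession_germ_sd=0.0, outlier_rate=0.0, seed=17,
        )
        curve = self._h2_curve(cfg)
        late = curve.loc[20:].mean()
        assert late == pytest.approx(0.4, abs=0.1)

    def test_rise_then_fall_with_late_noise_inflation(self):
        """Absolute noise dominates small plants and inflated late noise
        (leaf overlap) dominates large ones, so H2 rises then falls."""
        cfg = SimConfig(
            n_accessions=100, n_markers=60, n_days=40,
            temperature_phases=[(1, 10, 15.0, 15.0), (11, 20, 24.0, 19.0),
                                (21, 40, 32.0, 22.0)],
            polygenic_h2=0.5, measurement_noise_sd=0.05,
            additive_noise_sd=2.0, late_noise_inflation=4.0, overlap_day=32,
            nongerm_rate=0.0, germ_jitter=0, amax_cv=0.0, rate_cv=0.0,
            accession_germ_sd=0.0, outlier_rate=0.0, seed=19,
        )
        curve = self._h2_curve(cfg)
        early = curve.loc[4:8].mean()
        mid = curve.loc[24:30].mean()
        late = curve.loc[36:40].mean()
        assert mid > early + 0.1
        assert mid > late + 0.1
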