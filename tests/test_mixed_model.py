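import numpy as np
import pytest
from scipy import stats

from mitolink import mixed_model as mm, synthetic_data as sd
from mitolink.phenotype import PhenotypeMatrix
import pandas as pd

from conftest import make_table


def dense_reml_loglik(delta, y, X, K):
    """Direct dense-matrix REML log-likelihood (determinants and
    quadratic forms), independent of the spectral implementation."""
    n, q = X.shape
    H = K + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    P = Hi - Hi @ X @ np.linalg.inv(X.T @ Hi @ X) @ X.T @ Hi
    nq = n - q
    _, ld_h = np.linalg.slogdet(H)
    _, ld_xhx = np.linalg.slogdet(X.T @ Hi @ X)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi)) - nq + ld_xx - ld_h - ld_xhx
        - nq * np.log(y @ P @ y)
    )


def dense_gls_test(y, X, K, vc, g):
    """Per-SNP GLS with explicit dense covariance inversion, residual
    scale re-estimated with n - q - 1 df."""
    n, q = X.shape
    Sigma = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(n)
    Si = np.linalg.inv(Sigma)
    W = np.column_stack([X, g])
    A = np.linalg.inv(W.T @ Si @ W)
    beta = A @ W.T @ Si @ y
    resid = y - W @ beta
    df = n - q - 1
    sigma2 = (resid @ Si @ resid) / df
    se = np.sqrt(sigma2 * A[-1, -1])
    t = beta[-1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[-1], se, t, p


def structured_fixture(n=12, m=8, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    table = make_table(
        list(range(100, 100 + m)),
        [[0] * n] * m,
        [[0] * n] * m,
        total_depth=[[10] * n] * m,
        genotype=g.T.tolist(),
        contig="chr1",
        ref="A",
    )
    K = mm.compute_kinship(table).values
    y = rng.standard_normal(n)
    X = np.ones((n, 1))
    return y, X, K, table, g


class TestSnpFilter:
    def test_planted_violations_removed(self):
        rng = np.random.default_rng(1)
        n, m = 40, 100
        g = rng.binomial(2, 0.3, size=(m, n)).astype(float)
        low_maf = [3, 17, 50]
        over_missing = [5, 60, 61, 99]
        for i in low_maf:
            g[i] = 0.0
            g[i, 0] = 1.0  # MAF 1/80 < 0.05
        for i in over_missing:
            g[i, : int(0.45 * n)] = np.nan
        t = make_table(
            list(range(1, m + 1)), [[0] * n] * m, [[0] * n] * m,
            total_depth=[[10] * n] * m, genotype=g.tolist(), contig="chr1",
        )
        kept = mm.filter_nuclear_snps(t)
        assert kept.n_sites == m - 7
        kept_pos = set(kept.pos)
        for i in low_maf + over_missing:
            assert (i + 1) not in kept_pos

    def test_empty_output_is_error(self):
        t = make_table([1], [[0] * 4], [[0] * 4], total_depth=[[10] * 4],
                       genotype=[[0, 0, 0, 0]], contig="chr1")
        with pytest.raises(ValueError):
            mm.filter_nuclear_snps(t)


class TestKinship:
    def test_identical_vectors_give_one(self):
        g = np.tile([0, 1, 2, 1, 0], (2, 1)).astype(float)
        K = sd.ibs_kinship_from_dosage(g)
        assert K[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_give_zero(self):
        g = np.array([[0.0] * 6, [2.0] * 6])
        K = sd.ibs_kinship_from_dosage(g)
        assert K[0, 1] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        K = sd.ibs_kinship_from_dosage(g)
        for i in range(20):
            for j in range(20):
                expect = 1 - np.mean(np.abs(g[i] - g[j])) / 2
                assert K[i, j] == pytest.approx(expect, abs=1e-12)

    def test_mean_imputation_path_agrees_with_manual(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=(10, 30)).astype(float)
        g[rng.random(g.shape) < 0.1] = np.nan
        K = sd.ibs_kinship_from_dosage(g)
        gi = g.copy()
        mu = np.nanmean(gi, axis=0)
        idx = np.where(np.isnan(gi))
        gi[idx] = mu[idx[1]]
        expect = sd.ibs_kinship_from_dosage(gi)
        assert np.allclose(K, expect)

    def test_too_few_snps_rejected(self):
        t = make_table([1], [[0, 0]], [[0, 0]], total_depth=[[9, 9]],
                       genotype=[[1, 1]], contig="chr1")
        with pytest.raises(ValueError):
            mm.compute_kinship(t)


class TestVarianceComponents:
    def test_spectral_reml_matches_dense_at_ten_deltas(self):
        y, X, K, _, _ = structured_fixture(n=6, m=30, seed=5)
        lam, eta = mm._reml_spectrum(y, X, K)
        for delta in np.logspace(-2, 3, 10):
            spectral = mm.reml_loglik(delta, lam, eta)
            dense = dense_reml_loglik(delta, y, X, K)
            assert spectral == pytest.approx(dense, abs=1e-6)

    def test_pure_noise_pushes_delta_to_boundary(self):
        rng = np.random.default_rng(6)
        deltas, sg = [], []
        _, X, K, _, _ = structured_fixture(n=40, m=60, seed=7)
        for _ in range(50):
            y = rng.standard_normal(40)
            vc = mm.estimate_variance_components(y, X, K)
            deltas.append(vc.delta)
            sg.append(vc.sigma_g2)
        assert np.median(deltas) > 1e2
        assert np.median(sg) < 0.05

    def test_identity_kinship_recovers_total_variance(self):
        rng = np.random.default_rng(8)
        n = 80
        X = np.ones((n, 1))
        K = np.eye(n)
        ratios = []
        for _ in range(200):
            y = 2.0 * rng.standard_normal(n)
            vc = mm.estimate_variance_components(y, X, K)
            ratios.append((vc.sigma_g2 + vc.sigma_e2) / np.var(y, ddof=1))
        assert abs(np.median(ratios) - 1.0) < 0.10

    def test_constant_phenotype_rejected(self):
        _, X, K, _, _ = structured_fixture()
        with pytest.raises(ValueError):
            mm.estimate_variance_components(np.ones(12), X, K)


class TestGlsScan:
    def test_matches_dense_gls_oracle(self):
        y, X, K, table, g = structured_fixture(n=12, m=8, seed=9)
        vc = mm.estimate_variance_components(y, X, K)
        res = mm.gls_scan(y, X, K, vc, table)
        for j in range(g.shape[1]):
            if res["skipped"].iloc[j]:
                continue
            b, se, t, p = dense_gls_test(y, X, K, vc, g[:, j])
            assert res["beta"].iloc[j] == pytest.approx(b, abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(se, abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(p, abs=1e-8)

    def test_identity_kinship_reduces_to_ols(self):
        y, X, K, table, g = structured_fixture(n=15, m=10, seed=10)
        I = np.eye(15)
        vc = mm.estimate_variance_components(y, X, I)
        res = mm.gls_scan(y, X, I, vc, table)
        for j in range(g.shape[1]):
            if res["skipped"].iloc[j]:
                continue
            slope, _, _, p, _ = stats.linregress(g[:, j], y)
            assert res["beta"].iloc[j] == pytest.approx(slope, abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(p, abs=1e-8)

    def test_constant_snp_recorded_as_skipped(self):
        y, X, K, table, g = structured_fixture(n=10, m=5, seed=11)
        table.genotype[2, :] = 1.0
        res = mm.gls_scan(y, X, K, vc=mm.estimate_variance_components(y, X, K),
                          genotypes=table)
        assert bool(res["skipped"].iloc[2])
        assert np.isnan(res["p"].iloc[2])


class TestRunGwas:
    def _setup(self, seed=12, n=80, m=60, n_pheno=3):
        cfg = sd.SimulationConfig(
            n_individuals=n, n_nuclear_snps=m, seed=seed,
            causal_snp_index=None, beta=0.0,
        )
        nuclear, _ = sd.simulate_population(cfg)
        fr = sd.simulate_mito_fractions(nuclear.genotype.T, cfg, n_variants=n_pheno)
        mito = sd.simulate_read_counts(fr, 100, seed=seed, samples=nuclear.samples)
        from mitolink.phenotype import build_phenotype_matrix

        pheno = build_phenotype_matrix(mito)
        nuc = mm.filter_nuclear_snps(nuclear)
        K = mm.compute_kinship(nuc)
        return pheno, nuc, K

    def test_one_table_per_phenotype_same_snp_set(self):
        pheno, nuc, K = self._setup()
        results = mm.run_gwas(pheno, nuc, K)
        assert len(results) == 3
        tables = [t for t, _ in results.values()]
        for t in tables[1:]:
            assert np.array_equal(t["pos"].to_numpy(), tables[0]["pos"].to_numpy())

    def test_affine_phenotype_invariance(self):
        pheno, nuc, K = self._setup(seed=13, n_pheno=1)
        results = mm.run_gwas(pheno, nuc, K)
        (table, _), = results.values()
        shifted = PhenotypeMatrix(values=3.5 * pheno.values + 0.2)
        results2 = mm.run_gwas(shifted, nuc, K)
        (table2, _), = results2.values()
        assert np.allclose(
            table["p"].to_numpy(), table2["p"].to_numpy(),
            atol=1e-10, equal_nan=True,
        )

    def test_sparse_phenotype_skipped_with_warning(self):
        pheno, nuc, K = self._setup(seed=14, n_pheno=1)
        vals = pheno.values.copy()
        vals.iloc[0, 25:] = np.nan
        sparse = PhenotypeMatrix(values=vals)
        with pytest.warns(UserWarning):
            results = mm.run_gwas(sparse, nuc, K, min_samples=30)
        assert results == {}


class TestStratificationCorrection:
    def test_kinship_restores_calibration_identity_inflates(self):
        """Genomic-control lambda near 1 with K, inflated with identity,
        on one structured null cohort (reduced size for speed)."""
        cfg = sd.SimulationConfig(
            n_individuals=150, n_nuclear_snps=1200, fst=0.3, beta=0.0, seed=15
        )
        nuclear, _ = sd.simulate_population(cfg)
        fr = sd.simulate_mito_fractions(nuclear.genotype.T, cfg)
        mito = sd.simulate_read_counts(fr, 100, seed=15, samples=nuclear.samples)
        from mitolink.phenotype import build_phenotype_matrix

        y = build_phenotype_matrix(mito).values.iloc[0].to_numpy()
        nuc = mm.filter_nuclear_snps(nuclear)
        X = np.ones((len(y), 1))
        K = mm.compute_kinship(nuc).values

        def gc_lambda(p):
            p = p[~np.isnan(p)]
            return np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)

        vc = mm.estimate_variance_components(y, X, K)
        lam_k = gc_lambda(mm.gls_scan(y, X, K, vc, nuc)["p"].to_numpy())
        I = np.eye(len(y))
        vci = mm.estimate_variance_components(y, X, I)
        lam_i = gc_lambda(mm.gls_scan(y, X, I, vci, nuc)["p"].to_numpy())
        assert 0.8 < lam_k < 1.2
        assert lam_i > 1.2
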