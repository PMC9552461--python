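import numpy as np
import pytest

from pcaqtl.containers import CovariateMatrix
from pcaqtl.pca import (
    filter_known_covariates,
    infer_covariates,
    regress_out,
    run_pca,
)

from conftest import make_covariates, make_phenotypes


def max_offdiag_abs_cor(scores):
    c = np.corrcoef(scores, rowvar=False)
    return np.max(np.abs(c - np.diag(np.diag(c))))


class TestRunPCA:
    def test_rank_one_matrix_single_component(self, rng):
        col = rng.standard_normal(10)
        Y = make_phenotypes(np.column_stack([col, 2 * col, -0.5 * col]))
        res = run_pca(Y, center=True, scale=True)
        assert res.pve[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.pve[1:], 0, atol=1e-12)

    def test_scores_uncorrelated_and_pve_normalized(self, rng):
        Y = make_phenotypes(rng.standard_normal((30, 50)))
        res = run_pca(Y)
        assert max_offdiag_abs_cor(res.scores) < 1e-8
        assert np.sum(res.pve) == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.pve) <= 1e-12)

    def test_iid_noise_no_dominant_component(self):
        # Marchenko-Pastur-type bound: for 50 x 200 iid Gaussian data no
        # single PC should explain a large variance fraction
        for seed in range(20):
            Y = make_phenotypes(np.random.default_rng(seed).standard_normal((50, 200)))
            res = run_pca(Y)
            assert res.pve[0] < 0.2
            assert np.sum(res.pve) == pytest.approx(1.0, abs=1e-10)

    def test_pve_matches_correlation_eigenvalues(self, rng):
        Y = make_phenotypes(rng.standard_normal((40, 12)))
        res = run_pca(Y, center=True, scale=True)
        lam = np.sort(np.linalg.eigvalsh(np.corrcoef(Y.values, rowvar=False)))[::-1]
        np.testing.assert_allclose(res.pve, lam[: len(res.pve)] / lam.sum(), atol=1e-10)

    def test_row_permutation_equivariance(self, rng):
        Y = make_phenotypes(rng.standard_normal((25, 10)))
        perm = rng.permutation(25)
        Yp = make_phenotypes(Y.values[perm])
        a, b = run_pca(Y), run_pca(Yp)
        # same pve; permuted scores match up to sign (fixed by the loading
        # convention, so exactly)
        np.testing.assert_allclose(a.pve, b.pve, atol=1e-12)
        np.testing.assert_allclose(a.scores[perm], b.scores, atol=1e-8)

    def test_zero_variance_feature_with_scale_errors(self):
        Y = make_phenotypes(np.array([[1.0, 7], [2, 7], [3, 7]]))
        with pytest.raises(ValueError, match="zero-variance"):
            run_pca(Y, scale=True)

    def test_sign_convention_largest_loading_positive(self, rng):
        Y = make_phenotypes(rng.standard_normal((20, 8)))
        res = run_pca(Y)
        for k in range(res.n_components):
            lead = res.loadings[np.argmax(np.abs(res.loadings[:, k])), k]
            assert lead > 0


class TestRegressOut:
    def test_exact_covariate_gives_zero_residual(self, rng):
        x = rng.standard_normal(15)
        Y = make_phenotypes(np.column_stack([x, rng.standard_normal(15)]))
        X1 = make_covariates(x)
        resid = regress_out(Y, X1)
        assert np.max(np.abs(resid.values[:, 0])) < 1e-10

    def test_empty_covariates_center_only(self, rng):
        Y = make_phenotypes(rng.standard_normal((10, 3)) + 5.0)
        X1 = CovariateMatrix.empty(Y.sample_ids)
        resid = regress_out(Y, X1)
        np.testing.assert_allclose(resid.values, Y.values - Y.values.mean(axis=0), atol=1e-12)

    def test_matches_per_column_ols_oracle(self, rng):
        Y = make_phenotypes(rng.standard_normal((20, 5)))
        x = rng.standard_normal(20)
        resid = regress_out(Y, make_covariates(x))
        D = np.column_stack([np.ones(20), x])
        for j in range(5):
            coef, *_ = np.linalg.lstsq(D, Y.values[:, j], rcond=None)
            np.testing.assert_allclose(resid.values[:, j], Y.values[:, j] - D @ coef, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        Y = make_phenotypes(rng.standard_normal((30, 8)))
        X1 = make_covariates(rng.standard_normal((30, 3)))
        resid = regress_out(Y, X1)
        Xc = X1.values - X1.values.mean(axis=0)
        assert np.max(np.abs(Xc.T @ resid.values)) < 1e-8

    def test_rank_deficient_covariates_warn_and_proceed(self, rng):
        x = rng.standard_normal(12)
        X1 = make_covariates(np.column_stack([x, 2 * x]))
        Y = make_phenotypes(rng.standard_normal((12, 2)))
        with pytest.warns(UserWarning, match="collinear"):
            resid = regress_out(Y, X1)
        assert np.all(np.isfinite(resid.values))


class TestFilterKnownCovariates:
    def test_exact_capture_dropped(self, rng):
        Y = make_phenotypes(rng.standard_normal((25, 10)))
        pcs = run_pca(Y).scores_matrix(Y.sample_ids, 3)
        X1 = make_covariates(pcs.values[:, 0], prefix="known")
        res = filter_known_covariates(X1, pcs)
        assert res.dropped == ["known0"]
        assert res.r2["known0"] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_covariate_kept(self, rng):
        Y = make_phenotypes(rng.standard_normal((25, 10)))
        pca = run_pca(Y)
        pcs = pca.scores_matrix(Y.sample_ids, 3)
        # build a vector orthogonal to the PCs (and the intercept) by
        # projecting noise off of them
        basis = np.column_stack([np.ones(25), pcs.values])
        Q, _ = np.linalg.qr(basis)
        v = rng.standard_normal(25)
        v -= Q @ (Q.T @ v)
        res = filter_known_covariates(make_covariates(v, prefix="known"), pcs)
        assert res.dropped == []
        assert abs(res.r2["known0"]) < 1e-8

    def test_partial_capture_matches_ols_oracle(self, rng):
        Y = make_phenotypes(rng.standard_normal((50, 20)))
        pcs = run_pca(Y).scores_matrix(Y.sample_ids, 3)
        pc1 = pcs.values[:, 0] / pcs.values[:, 0].std()
        noise = rng.standard_normal(50)
        cov = 0.95 * pc1 + 0.05 * noise / noise.std()
        X1 = make_covariates(cov, prefix="known")
        res = filter_known_covariates(X1, pcs)
        # brute-force unadjusted R^2 for this instance
        D = np.column_stack([np.ones(50), pcs.values])
        coef, *_ = np.linalg.lstsq(D, cov, rcond=None)
        r2_oracle = 1 - np.sum((cov - D @ coef) ** 2) / np.sum((cov - cov.mean()) ** 2)
        assert res.r2["known0"] == pytest.approx(r2_oracle, abs=1e-12)
        assert r2_oracle > 0.9
        assert res.dropped == ["known0"]


class TestInferCovariates:
    def test_variants_agree_without_known_covariates(self, rng):
        Y = make_phenotypes(rng.standard_normal((20, 15)))
        X1 = CovariateMatrix.empty(Y.sample_ids)
        a = infer_covariates(Y, X1, "pca_direct", K=4)
        b = infer_covariates(Y, X1, "pca_resid", K=4)
        # residualizing on nothing = centering, so scores agree up to sign
        np.testing.assert_allclose(
            np.abs(a.X_inferred.values), np.abs(b.X_inferred.values), atol=1e-8
        )

    def test_hidden_factor_recovery(self):
        # Y driven by 3 strong hidden covariates: top-3 PCs must capture them
        from pcaqtl.evaluate import concordance
        from pcaqtl.simulate import SimParams, simulate_design2

        scores = []
        for seed in range(10):
            d = simulate_design2(
                SimParams(n=100, p=150, snps_per_gene=5, num_covariates=3,
                          pve_covariates=0.6, pve_genotype=0.05, seed=seed)
            )
            res = infer_covariates(d.Y, d.X1, "pca_direct", K=3)
            scores.append(concordance(d.X2, res.X_inferred).concordance)
        assert np.mean(scores) > 0.9

    def test_pca_resid_removes_known_covariate(self, rng):
        from pcaqtl.evaluate import concordance

        n, p = 60, 80
        hidden = rng.standard_normal((n, 2))
        load = rng.standard_normal((2, p))
        Y = make_phenotypes(hidden @ load + 0.3 * rng.standard_normal((n, p)))
        X1 = make_covariates(hidden[:, 0], prefix="known")
        res = infer_covariates(Y, X1, "pca_resid", K=2)
        # the PCs of the residualized data no longer contain covariate 0:
        # reverse adjusted R^2 of that covariate on the PCs is near zero
        c = concordance(X1, res.X_inferred)
        assert c.adj_r2_score < 0.05
        assert res.X1_used.covariate_ids == ["known0"]  # unfiltered

    def test_k_out_of_range(self, gaussian_pheno):
        X1 = CovariateMatrix.empty(gaussian_pheno.sample_ids)
        with pytest.raises(ValueError, match="out of range"):
            infer_covariates(gaussian_pheno, X1, "pca_direct", K=0)
        with pytest.raises(ValueError, match="out of range"):
            infer_covariates(gaussian_pheno, X1, "pca_direct", K=1000)
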