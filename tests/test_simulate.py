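import numpy as np
import pytest
from scipy.stats import kstest

from pcaqtl.qtl import map_qtl
from pcaqtl.simulate import (
    SimParams,
    _scale_to_share,
    benchmark_grid,
    simulate_design1,
    simulate_design2,
    simulate_genotypes,
    spiked_phenotypes,
)


class TestSimulateGenotypes:
    def test_no_ld_gives_uncorrelated_neighbors(self):
        G = simulate_genotypes(200, 500, ld_rho=0.0, seed=11)
        cors = [
            np.corrcoef(G.dosages[:, j], G.dosages[:, j + 1])[0, 1]
            for j in range(G.n_snps - 1)
        ]
        assert abs(np.mean(cors)) < 0.05

    def test_strong_ld_gives_correlated_neighbors(self):
        G = simulate_genotypes(200, 500, ld_rho=0.9, seed=11)
        cors = [
            abs(np.corrcoef(G.dosages[:, j], G.dosages[:, j + 1])[0, 1])
            for j in range(G.n_snps - 1)
        ]
        assert np.median(cors) > 0.5

    def test_empirical_maf_tracks_target(self):
        G = simulate_genotypes(200, 300, maf_range=(0.1, 0.4), seed=5)
        assert np.all(G.maf >= 0.1 - 0.15) and np.all(G.maf <= 0.5)
        assert G.dosages.min() >= 0 and G.dosages.max() <= 2

    def test_seeded_determinism(self):
        a = simulate_genotypes(50, 30, seed=9)
        b = simulate_genotypes(50, 30, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimParams(ld_rho=1.0)
        with pytest.raises(ValueError):
            SimParams(pve_genotype=0.6, pve_covariates=0.5)


class TestVarianceBookkeeping:
    def test_scale_to_share_is_exact(self, rng):
        for share in (0.1, 0.4, 0.85):
            x = rng.standard_normal(100) * 3 + 2
            scaled = _scale_to_share(x, share)
            assert scaled.var(ddof=1) == pytest.approx(share, abs=1e-12)
            assert scaled.mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_share_zeroes_component(self, rng):
        np.testing.assert_array_equal(_scale_to_share(rng.standard_normal(20), 0.0), 0.0)

    def test_constant_component_with_positive_share_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            _scale_to_share(np.ones(10), 0.3)

    def test_unit_total_variance_per_gene(self):
        d = simulate_design2(SimParams(n=80, p=20, snps_per_gene=5, seed=0))
        # components have exact shares; their sum's variance deviates only
        # by sampling cross-covariances
        v = d.Y.values.var(axis=0, ddof=1)
        assert np.all(np.abs(v - 1.0) < 0.35)
        assert (d.realized_pve.sum(axis=1) == 1.0).all()


class TestDesign2:
    def test_truth_pairs_lie_in_cis_blocks(self):
        d = simulate_design2(SimParams(n=50, p=10, snps_per_gene=6, num_effect_snps=2, seed=3))
        assert len(d.truth) == 20
        for _, row in d.truth.iterrows():
            snp_idx = d.G.snp_ids.index(row["snp_id"])
            assert snp_idx in d.G.cis_map[row["feature_id"]]
        assert (d.truth["kind"] == "cis").all()

    def test_coordinates_reproduce_cis_blocks(self):
        from pcaqtl.io_preprocess import build_cis_map

        d = simulate_design2(SimParams(n=30, p=5, snps_per_gene=4, seed=2))
        rebuilt = build_cis_map(d.G.snp_coords, d.Y.feature_coords, 1_000_000)
        for f in d.Y.feature_ids:
            np.testing.assert_array_equal(rebuilt[f], d.G.cis_map[f])

    def test_known_hidden_split(self):
        d = simulate_design2(
            SimParams(n=50, p=10, snps_per_gene=4, num_covariates=5, k1_known=2, seed=1)
        )
        assert d.X1.n_covariates == 2 and d.X1.role == "known"
        assert d.X2.n_covariates == 3 and d.X2.role == "hidden_truth"

    def test_zero_genotype_pve_gives_uniform_pvalues(self):
        pvals = []
        for seed in range(3):
            d = simulate_design2(
                SimParams(n=100, p=60, snps_per_gene=5, pve_genotype=0.0, seed=seed)
            )
            from pcaqtl.containers import CovariateMatrix

            ideal = CovariateMatrix(
                d.X2.values, d.Y.sample_ids, d.X2.covariate_ids
            )
            pvals.append(map_qtl(d.Y, d.G, ideal, scope="cis").table["p_value"].to_numpy())
        pvals = np.concatenate(pvals)
        assert kstest(pvals, "uniform").statistic < 0.05

    def test_seeded_determinism(self):
        a = simulate_design2(SimParams(n=40, p=8, snps_per_gene=4, seed=21))
        b = simulate_design2(SimParams(n=40, p=8, snps_per_gene=4, seed=21))
        np.testing.assert_array_equal(a.Y.values, b.Y.values)
        assert a.truth.equals(b.truth)

    def test_excess_causal_snps_rejected(self):
        with pytest.raises(ValueError):
            SimParams(snps_per_gene=3, num_effect_snps=5)


class TestDesign1:
    def base(self, **kw):
        kw.setdefault("n", 120)
        kw.setdefault("p", 60)
        kw.setdefault("snps_per_gene", 5)
        kw.setdefault("design", "design1")
        kw.setdefault("num_factors", 4)
        kw.setdefault("num_trans_hotspots", 2)
        kw.setdefault("pve_trans", 0.6)
        kw.setdefault("pve_genotype", 0.1)
        kw.setdefault("pve_covariates", 0.1)
        return SimParams(**kw)

    def test_trans_signal_pervades(self):
        hits = []
        for seed in range(3):
            d = simulate_design1(self.base(n=200, seed=seed))
            hotspots = d.truth.loc[d.truth["kind"] == "trans", "snp_id"].unique()
            res = map_qtl(d.Y, d.G, scope="all_pairs")
            for h in hotspots:
                sub = res.table[res.table["snp_id"] == h]
                hits.append((sub["p_value"] < 0.01).mean())
        assert np.mean(hits) >= 0.3

    def test_degenerates_to_cis_only(self):
        d = simulate_design1(self.base(num_trans_hotspots=0, pve_trans=0.0, num_factors=0, seed=4))
        assert set(d.truth["kind"]) == {"cis"}
        assert len(d.truth) == 60

    def test_truth_labels_both_kinds(self):
        d = simulate_design1(self.base(seed=5))
        kinds = d.truth["kind"].value_counts()
        assert kinds["cis"] == 60
        assert kinds["trans"] == 60 * 2

    def test_seeded_determinism(self):
        a = simulate_design1(self.base(seed=6))
        b = simulate_design1(self.base(seed=6))
        np.testing.assert_array_equal(a.Y.values, b.Y.values)

    def test_overcommitted_pve_rejected(self):
        with pytest.raises(ValueError, match="sum to < 1"):
            self.base(pve_trans=0.9)


class TestSpikedPhenotypes:
    def test_exact_factor_shares(self):
        Y = spiked_phenotypes(50, 20, num_factors=3, pve_per_factor=0.15, seed=0)
        assert np.all(np.abs(Y.values.var(axis=0, ddof=1) - 1.0) < 0.6)
        # each feature has rank-3 structure worth 45% of its variance


class TestBenchmarkGrid:
    BASE = dict(n=60, p=40, snps_per_gene=4, num_covariates=3, k1_known=1)

    def test_row_bookkeeping(self):
        table = benchmark_grid(
            SimParams(**self.BASE),
            {"pve_covariates": [0.1, 0.2, 0.3, 0.4]},
            replicates=2,
            methods=("ideal", "unadjusted"),
            seed=1,
        )
        assert len(table) == 4 * 2 * 2
        assert set(table["method"]) == {"ideal", "unadjusted"}
        assert table.loc[table["method"] == "ideal", "concordance"].isna().all()

    def test_seeded_reproducibility(self):
        args = (SimParams(**self.BASE), {"pve_covariates": [0.3]})
        a = benchmark_grid(*args, replicates=2, methods=("ideal", "pca_direct"), seed=7)
        b = benchmark_grid(*args, replicates=2, methods=("ideal", "pca_direct"), seed=7)
        assert a.drop(columns="runtime_s").equals(b.drop(columns="runtime_s"))

    def test_unknown_method_rejected_before_simulation(self):
        with pytest.raises(ValueError, match="unknown method"):
            benchmark_grid(SimParams(**self.BASE), {}, methods=("ideal", "peer"), seed=1)

    def test_ideal_beats_unadjusted_when_confounded(self):
        table = benchmark_grid(
            SimParams(n=100, p=80, snps_per_gene=5, num_covariates=3, k1_known=0,
                      pve_covariates=0.5, pve_genotype=0.1),
            {},
            replicates=4,
            methods=("ideal", "unadjusted"),
            seed=3,
        )
        means = table.groupby("method")["auprc"].mean()
        assert means["ideal"] > means["unadjusted"]

    def test_external_method_reads_covariate_file(self, tmp_path):
        from dataclasses import replace

        from pcaqtl.io_preprocess import write_covariates
        from pcaqtl.simulate import simulate as sim

        params = SimParams(n=60, p=30, snps_per_gene=4)
        # reproduce the replicate seed the grid will derive from seed=10
        rep_seed = int(np.random.SeedSequence(10).spawn(1)[0].generate_state(1)[0] % 2**31)
        d = sim(replace(params, seed=rep_seed))
        path = tmp_path / "external.tsv"
        write_covariates(d.X2, path)
        table = benchmark_grid(
            params, {}, replicates=1, methods=(f"external:{path}",), seed=10
        )
        assert len(table) == 1
        # supplying the true hidden covariates is as good as Ideal
        assert table["concordance"].iloc[0] > 0.99
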