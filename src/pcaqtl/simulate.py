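"""Synthetic QTL data sets with ground truth, and the benchmark grid.

Two generative designs are implemented, sharing the same variance
bookkeeping: each gene's phenotype is a sum of a genetic component, a
covariate component, (in Design 1) a trans-regulatory component, and
Gaussian noise, with the components rescaled so that their realized
sample-variance shares match the requested proportions of variance
explained (PVE) exactly.

* Design 2 (the main benchmark): cis-regulation only. Each gene owns a
  disjoint block of cis SNPs; a configurable number of them are causal
  with N(0, 1) effect sizes. Known and hidden covariates are N(0, 1)
  values shared across genes with per-gene N(0, 1) loadings.
* Design 1: expression is dominated by dense trans effects. Latent
  factors load on all genes; some factors are partially driven by
  "hotspot" SNPs, so every gene acquires a trans association with every
  hotspot. Sparse cis effects (one causal SNP per gene) and covariates
  fill out the variance.

Genotype dosages are generated from paired haplotypes whose alleles come
from a latent first-order (AR(1)) Gaussian copula thresholded at each
SNP's target minor-allele frequency, giving tunable neighbor LD.
"""
from __future__ import annotations

import time
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .containers import CovariateMatrix, GenotypeData, PhenotypeMatrix

GENE_SPACING = 4_000_000  # bp between gene starts; keeps cis windows disjoint
SNP_SPACING = 1_000
DEFAULT_SIM_CIS_WINDOW = 1_000_000


@dataclass
class SimParams:
    """Parameters of a simulated QTL data set.

    Defaults define the package's reference benchmark cell: 200 samples,
    500 genes with 50 cis SNPs each, one causal cis SNP per gene, three
    hidden covariates and no known ones, genotype PVE 0.1 and covariate
    PVE 0.4 per gene (noise takes the remaining half). Design 1 adds
    latent trans factors with their own variance share.
    """

    n: int = 200
    p: int = 500
    snps_per_gene: int = 50
    num_effect_snps: int = 1
    num_covariates: int = 3
    k1_known: int = 0
    pve_genotype: float = 0.1
    pve_covariates: float = 0.4
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5
    design: str = "design2"
    # Design 1 extras
    num_factors: int = 10
    num_trans_hotspots: int = 3
    pve_trans: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        extra = self.pve_trans if self.design == "design1" else 0.0
        if self.pve_genotype + self.pve_covariates + extra >= 1.0:
            raise ValueError("PVE shares must sum to < 1 (remainder is noise)")
        if not (0 <= self.pve_genotype and 0 <= self.pve_covariates):
            raise ValueError("PVE shares must be non-negative")
        if self.num_effect_snps > self.snps_per_gene:
            raise ValueError("more causal SNPs requested than cis SNPs per gene")
        if self.k1_known > self.num_covariates:
            raise ValueError("k1_known exceeds num_covariates")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.design not in ("design1", "design2"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class SimulatedDataset:
    Y: PhenotypeMatrix
    G: GenotypeData
    X1: CovariateMatrix
    X2: CovariateMatrix
    truth: pd.DataFrame  # columns feature_id, snp_id, effect_size, kind
    realized_pve: pd.DataFrame  # per-gene variance shares of each component
    params: SimParams = None

    @property
    def truth_pairs(self) -> list:
        return list(zip(self.truth["feature_id"], self.truth["snp_id"]))


def simulate_genotypes(
    n: int,
    total_snps: int,
    maf_range: tuple = (0.05, 0.5),
    ld_rho: float = 0.5,
    seed=None,
    chrom: str = "1",
    start_pos: int = 1,
) -> GenotypeData:
    """Generate dosages for ``n`` diploid samples at ``total_snps`` SNPs.

    Per-SNP target MAFs are Uniform(maf_range). Each of the 2n haplotypes
    carries alleles obtained by thresholding a latent AR(1) Gaussian chain
    with neighbor correlation ``ld_rho`` at the SNP's MAF quantile, so
    adjacent SNPs are in LD while marginal frequencies are preserved.
    """
    rng = np.random.default_rng(seed)
    maf_target = rng.uniform(maf_range[0], maf_range[1], size=total_snps)
    from scipy.special import ndtri

    thresh = ndtri(maf_target)
    H = 2 * n
    # stationary AR(1) chain along the SNP axis: z_j = rho z_{j-1} + w_j
    W = rng.standard_normal((H, total_snps))
    if total_snps > 1 and ld_rho > 0:
        W[:, 1:] *= np.sqrt(1.0 - ld_rho**2)
        from scipy.signal import lfilter

        Z = lfilter([1.0], [1.0, -ld_rho], W, axis=1)
    else:
        Z = W
    alleles = Z < thresh
    dosages = np.add(alleles[0::2], alleles[1::2], dtype=float)

    alt_freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    snp_ids = [f"snp{j}" for j in range(total_snps)]
    pos = start_pos + SNP_SPACING * np.arange(total_snps)
    coords = pd.DataFrame({"chrom": chrom, "pos": pos}, index=snp_ids)
    sample_ids = [f"sample{i}" for i in range(n)]
    return GenotypeData(dosages, sample_ids, snp_ids, coords, maf, {})


def spiked_phenotypes(
    n: int,
    p: int,
    num_factors: int = 5,
    pve_per_factor: float = 0.1,
    seed=None,
) -> PhenotypeMatrix:
    """Low-rank 'spiked' phenotype matrix for calibrating K selection.

    Each of ``num_factors`` latent N(0,1) factors contributes exactly
    ``pve_per_factor`` of every feature's variance (loadings N(0,1),
    rescaled per feature); the remainder is Gaussian noise.
    """
    if not 0 < num_factors * pve_per_factor < 1:
        raise ValueError("factor variance shares must sum to within (0, 1)")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, num_factors))
    L = rng.standard_normal((p, num_factors))
    noise_share = 1.0 - num_factors * pve_per_factor
    Y = np.empty((n, p))
    eps = rng.standard_normal((n, p))
    for j in range(p):
        Y[:, j] = sum(
            _scale_to_share(F[:, k] * L[j, k], pve_per_factor) for k in range(num_factors)
        ) + _scale_to_share(eps[:, j], noise_share)
    sample_ids = [f"sample{i}" for i in range(n)]
    return PhenotypeMatrix(Y, sample_ids, [f"feature{j}" for j in range(p)])


def _scale_to_share(component: np.ndarray, share: float) -> np.ndarray:
    """Center a component and scale its ddof=1 sample variance to ``share``.

    A zero share zeroes the component; a positive share with a constant
    component is an error (the requested variance cannot be realized).
    """
    c = component - component.mean()
    if share == 0.0:
        return np.zeros_like(c)
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate component: cannot realize a positive variance share")
    return c * (np.sqrt(share) / sd)


def _make_covariates(rng, n: int, params: SimParams):
    X = rng.standard_normal((n, params.num_covariates))
    sample_ids = [f"sample{i}" for i in range(n)]
    X1 = CovariateMatrix(
        X[:, : params.k1_known],
        sample_ids,
        [f"known{i + 1}" for i in range(params.k1_known)],
        role="known",
    )
    X2 = CovariateMatrix(
        X[:, params.k1_known :],
        sample_ids,
        [f"hidden{i + 1}" for i in range(params.num_covariates - params.k1_known)],
        role="hidden_truth",
    )
    return X, X1, X2


def _gene_layout(params: SimParams):
    """Disjoint per-gene cis blocks and matching genomic coordinates.

    Gene starts are spaced far enough apart that each gene's block of
    ``snps_per_gene`` SNPs (1 kb apart, starting at the gene start) is the
    exact set a +/- 1 Mb cis-window lookup recovers.
    """
    q = params.snps_per_gene
    if q * SNP_SPACING > DEFAULT_SIM_CIS_WINDOW:
        raise ValueError("cis block wider than the cis window; reduce snps_per_gene")
    feature_ids = [f"gene{j}" for j in range(params.p)]
    starts = 1 + GENE_SPACING * np.arange(params.p)
    coords = pd.DataFrame(
        {"chrom": "1", "start": starts, "end": starts + 1}, index=feature_ids
    )
    cis_map = {f: np.arange(j * q, (j + 1) * q) for j, f in enumerate(feature_ids)}
    snp_pos = (starts[:, None] + SNP_SPACING * np.arange(q)[None, :]).ravel()
    return feature_ids, coords, cis_map, snp_pos


def simulate_design2(params: SimParams) -> SimulatedDataset:
    """Cis-regulation benchmark data set with exact per-gene PVE shares."""
    if params.design != "design2":
        raise ValueError("params.design must be 'design2'")
    rng = np.random.default_rng(params.seed)
    n, p, q = params.n, params.p, params.snps_per_gene
    feature_ids, coords, cis_map, snp_pos = _gene_layout(params)

    G = simulate_genotypes(
        n, p * q, params.maf_range, params.ld_rho, seed=rng.integers(2**31)
    )
    G.cis_map = cis_map
    G.snp_coords = pd.DataFrame({"chrom": "1", "pos": snp_pos}, index=G.snp_ids)
    X, X1, X2 = _make_covariates(rng, n, params)

    pve_noise = 1.0 - params.pve_genotype - params.pve_covariates
    Y = np.empty((n, p))
    truth_rows = []
    pve_rows = []
    for j, feat in enumerate(feature_ids):
        block = cis_map[feat]
        causal = rng.choice(q, size=params.num_effect_snps, replace=False)
        beta = rng.standard_normal(params.num_effect_snps)
        gamma = rng.standard_normal(params.num_covariates)
        g = G.dosages[:, block[causal]] @ beta
        c = X @ gamma if params.num_covariates else np.zeros(n)
        eps = rng.standard_normal(n)
        Y[:, j] = (
            _scale_to_share(g, params.pve_genotype)
            + _scale_to_share(c, params.pve_covariates)
            + _scale_to_share(eps, pve_noise)
        )
        for s_local, b in zip(causal, beta):
            truth_rows.append((feat, G.snp_ids[block[s_local]], b, "cis"))
        pve_rows.append((feat, params.pve_genotype, params.pve_covariates, 0.0, pve_noise))

    truth = pd.DataFrame(truth_rows, columns=["feature_id", "snp_id", "effect_size", "kind"])
    realized = pd.DataFrame(
        pve_rows, columns=["feature_id", "genotype", "covariates", "trans", "noise"]
    ).set_index("feature_id")
    Ym = PhenotypeMatrix(Y, G.sample_ids, feature_ids, coords)
    return SimulatedDataset(Ym, G, X1, X2, truth, realized, params)


def simulate_design1(params: SimParams) -> SimulatedDataset:
    """Trans-dominated data set: hotspot SNPs drive latent factors that
    load densely on all genes."""
    if params.design != "design1":
        raise ValueError("params.design must be 'design1'")
    rng = np.random.default_rng(params.seed)
    n, p, q = params.n, params.p, params.snps_per_gene
    if params.num_trans_hotspots > params.num_factors:
        raise ValueError("more hotspots than factors")
    feature_ids, coords, cis_map, snp_pos = _gene_layout(params)

    G = simulate_genotypes(
        n, p * q, params.maf_range, params.ld_rho, seed=rng.integers(2**31)
    )
    G.cis_map = cis_map
    G.snp_coords = pd.DataFrame({"chrom": "1", "pos": snp_pos}, index=G.snp_ids)
    X, X1, X2 = _make_covariates(rng, n, params)

    # latent factors; the first num_trans_hotspots are partially genetic
    F = rng.standard_normal((n, params.num_factors))
    hotspot_idx = (
        rng.choice(G.n_snps, size=params.num_trans_hotspots, replace=False)
        if params.num_trans_hotspots
        else np.array([], dtype=int)
    )
    for k, s in enumerate(hotspot_idx):
        d = G.dosages[:, s]
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("monomorphic hotspot SNP; reduce maf_range lower bound")
        # hotspot explains half of its factor's variance
        F[:, k] = np.sqrt(0.5) * (d - d.mean()) / sd + np.sqrt(0.5) * F[:, k]
    Lambda = rng.standard_normal((p, params.num_factors))

    pve_noise = 1.0 - params.pve_genotype - params.pve_covariates - params.pve_trans
    Y = np.empty((n, p))
    truth_rows = []
    pve_rows = []
    for j, feat in enumerate(feature_ids):
        block = cis_map[feat]
        causal = int(rng.integers(q))
        beta = float(rng.standard_normal())
        gamma = rng.standard_normal(params.num_covariates)
        g = G.dosages[:, block[causal]] * beta
        c = X @ gamma if params.num_covariates else np.zeros(n)
        t = F @ Lambda[j] if params.num_factors else np.zeros(n)
        eps = rng.standard_normal(n)
        Y[:, j] = (
            _scale_to_share(g, params.pve_genotype)
            + _scale_to_share(c, params.pve_covariates)
            + (_scale_to_share(t, params.pve_trans) if params.pve_trans > 0 else 0.0)
            + _scale_to_share(eps, pve_noise)
        )
        truth_rows.append((feat, G.snp_ids[block[causal]], beta, "cis"))
        for s in hotspot_idx:
            truth_rows.append((feat, G.snp_ids[s], np.nan, "trans"))
        pve_rows.append(
            (feat, params.pve_genotype, params.pve_covariates, params.pve_trans, pve_noise)
        )

    truth = pd.DataFrame(truth_rows, columns=["feature_id", "snp_id", "effect_size", "kind"])
    realized = pd.DataFrame(
        pve_rows, columns=["feature_id", "genotype", "covariates", "trans", "noise"]
    ).set_index("feature_id")
    Ym = PhenotypeMatrix(Y, G.sample_ids, feature_ids, coords)
    return SimulatedDataset(Ym, G, X1, X2, truth, realized, params)


def simulate(params: SimParams) -> SimulatedDataset:
    return simulate_design1(params) if params.design == "design1" else simulate_design2(params)


# ---------------------------------------------------------------------------
# benchmark grid

KNOWN_METHODS = ("ideal", "unadjusted", "pca_direct", "pca_resid", "hcp")


def _covariates_for_method(method: str, data: SimulatedDataset, K: int | None, seed):
    """Return (covariate matrix for map_qtl, inferred matrix or None, runtime)."""
    from .choose_k import be_select, elbow_select
    from .hcp import fit_hcp
    from .io_preprocess import transform
    from .pca import infer_covariates, run_pca

    X1, X2 = data.X1, data.X2
    sample_ids = data.Y.sample_ids

    def cat(*mats):
        mats = [m for m in mats if m is not None and m.n_covariates > 0]
        if not mats:
            return CovariateMatrix.empty(sample_ids)
        vals = np.column_stack([m.values for m in mats])
        ids = [c for m in mats for c in m.covariate_ids]
        return CovariateMatrix(vals, sample_ids, ids, role="known")

    t0 = time.perf_counter()
    if method == "ideal":
        return cat(X1, X2), None, 0.0
    if method == "unadjusted":
        return cat(X1), None, 0.0

    Yt = transform(data.Y, "center_scale")
    if K is None:  # default K policy: the true number of hidden covariates
        K = max(X2.n_covariates, 1)
    elif isinstance(K, str):
        pca_full = run_pca(Yt, center=True, scale=True)
        if K == "elbow":
            K = max(elbow_select(pca_full.pve).K, 1)
        elif K == "be":
            K = max(be_select(Yt, seed=seed).K, 1)
        else:
            raise ValueError(f"unknown K policy {K!r}")

    if method in ("pca_direct", "pca_resid"):
        res = infer_covariates(Yt, X1, variant=method, K=K)
        rt = time.perf_counter() - t0
        return cat(res.X1_used, res.X_inferred), res.X_inferred, rt
    if method == "hcp":
        # HCP needs a nonempty prior matrix; fall back to an intercept-like
        # standard normal column when no known covariates exist
        X1h = X1
        if X1h.n_covariates == 0:
            rng = np.random.default_rng(seed)
            X1h = CovariateMatrix(
                rng.standard_normal((len(sample_ids), 1)), sample_ids, ["prior1"]
            )
        fit = fit_hcp(Yt, X1h, K=K)
        Zm = fit.components(sample_ids)
        rt = time.perf_counter() - t0
        return cat(X1, Zm), Zm, rt
    if method.startswith("external:"):
        from .io_preprocess import read_covariates
        from .pca import filter_known_covariates

        ext = read_covariates(method.split(":", 1)[1], role="inferred")
        ext = ext.subset_samples(sample_ids)
        X1_used = filter_known_covariates(X1, ext).kept if X1.n_covariates else X1
        return cat(X1_used, ext), ext, time.perf_counter() - t0
    raise ValueError(f"unknown method {method!r}")


def benchmark_grid(
    base: SimParams,
    grid: dict,
    replicates: int = 2,
    methods=("ideal", "unadjusted", "pca_direct"),
    seed=None,
    K: int | str | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run the simulation benchmark over a parameter grid.

    ``grid`` maps SimParams field names to level lists; every combination
    (cell) is simulated ``replicates`` times and each method is scored by
    AUPRC, power (BH at ``fdr``), and the concordance scores. Returns a
    long-format table with one row per (cell, replicate, method).
    """
    from dataclasses import replace as dc_replace

    from .evaluate import evaluate_run
    from .qtl import map_qtl

    for m in methods:
        if m not in KNOWN_METHODS and not str(m).startswith("external:"):
            raise ValueError(f"unknown method {m!r}")

    axes = sorted(grid)
    cells = list(product(*(grid[a] for a in axes))) if axes else [()]
    ss = np.random.SeedSequence(seed)
    rows = []
    for cell in cells:
        overrides = dict(zip(axes, cell))
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            params = dc_replace(base, seed=rep_seed, **overrides)
            data = simulate(params)
            # Design 1 truth includes trans pairs, which only an
            # exhaustive pass can test
            scope = "cis" if params.design == "design2" else "all_pairs"
            for method in methods:
                Xm, inferred, runtime = _covariates_for_method(method, data, K, rep_seed)
                result = map_qtl(data.Y, data.G, Xm, scope=scope)
                rep_eval = evaluate_run(
                    result,
                    data.truth_pairs,
                    true_hidden=data.X2 if inferred is not None else None,
                    inferred=inferred,
                    power_rule={"bh_fdr": fdr},
                )
                row = {a: v for a, v in overrides.items()}
                row.update(
                    replicate=rep,
                    method=method,
                    auprc=rep_eval.auprc,
                    power=rep_eval.power,
                    adj_r2=rep_eval.adj_r2_score,
                    rev_adj_r2=rep_eval.rev_adj_r2_score,
                    concordance=rep_eval.concordance,
                    runtime_s=runtime,
                )
                rows.append(row)
    return pd.DataFrame(rows)
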