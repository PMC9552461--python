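"""Nominal-pass cis-QTL engine: per (phenotype, SNP) linear regression
with covariates.

For feature j and SNP l the model is

    Y[, j] ~ 1 + dosage_l + X

and the dosage coefficient's estimate, standard error, t statistic, and
two-sided p-value are retained. Computation uses Frisch-Waugh-Lovell
residualization: the covariates (plus intercept) are projected out of all
phenotypes and all dosage vectors once, after which each pair reduces to
a simple regression on residuals with df = n - (#covariates + 2). This is
algebraically identical to the full regression (the Matrix eQTL
strategy). Multiple testing is controlled by Benjamini-Hochberg over the
emitted rows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CovariateMatrix, GenotypeData, PhenotypeMatrix

logger = logging.getLogger(__name__)

MONOMORPHIC_VAR = 1e-12


@dataclass
class QTLResultTable:
    """One row per tested (feature, SNP) pair.

    Columns: feature_id, snp_id, beta (effect per alt-allele dosage), se,
    t_stat, p_value, q_value. Rows whose design was degenerate in-sample
    (e.g. a monomorphic SNP) carry NaN statistics and are excluded from
    the BH adjustment.
    """

    table: pd.DataFrame
    covariate_ids: list = field(default_factory=list)
    n: int = 0
    df: int = 0

    def __len__(self) -> int:
        return len(self.table)


def map_qtl(
    Y: PhenotypeMatrix,
    G: GenotypeData,
    X: CovariateMatrix | None = None,
    scope: str = "cis",
    bh_scope: str = "global",
) -> QTLResultTable:
    """Run the nominal association pass.

    ``scope='cis'`` tests each feature against the SNPs in its cis map;
    ``scope='all_pairs'`` tests every feature against every SNP.
    ``bh_scope`` selects BH adjustment over all rows (default) or within
    each feature.
    """
    if X is None:
        X = CovariateMatrix.empty(Y.sample_ids)
    if Y.sample_ids != G.sample_ids or Y.sample_ids != X.sample_ids:
        raise ValueError("inputs are not sample-aligned")
    if scope not in ("cis", "all_pairs"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "cis" and not G.cis_map:
        raise ValueError("cis scope requires a cis map on the genotype data")

    n = Y.n_samples
    from .pca import prune_collinear

    D = prune_collinear(np.column_stack([np.ones(n), X.values]), warn=False)
    n_cov = D.shape[1] - 1  # covariates actually in the design
    df = n - (n_cov + 2)
    if df < 1:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")

    Q, _ = np.linalg.qr(D)
    Ry = Y.values - Q @ (Q.T @ Y.values)
    Rg = G.dosages - Q @ (Q.T @ G.dosages)
    gss = np.sum(Rg**2, axis=0)
    yss = np.sum(Ry**2, axis=0)

    feats, snps, betas, ses, tstats, pvals = [], [], [], [], [], []
    n_skipped = 0
    for j, feat in enumerate(Y.feature_ids):
        idx = (
            np.asarray(G.cis_map.get(feat, []), dtype=int)
            if scope == "cis"
            else np.arange(G.n_snps)
        )
        if idx.size == 0:
            continue
        g2 = gss[idx]
        ok = g2 > MONOMORPHIC_VAR * n
        cross = Rg[:, idx].T @ Ry[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, cross / g2, np.nan)
            rss = yss[j] - beta**2 * g2
            sigma2 = np.maximum(rss, 0.0) / df
            se = np.sqrt(sigma2 / g2)
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
        n_skipped += int((~ok).sum())
        feats.extend([feat] * idx.size)
        snps.extend(G.snp_ids[i] for i in idx)
        betas.append(np.where(ok, beta, np.nan))
        ses.append(np.where(ok, se, np.nan))
        tstats.append(np.where(ok, t, np.nan))
        pvals.append(p)

    if n_skipped:
        logger.info("skipped %d pairs with (near-)monomorphic dosage in-sample", n_skipped)
    table = pd.DataFrame(
        {
            "feature_id": feats,
            "snp_id": snps,
            "beta": np.concatenate(betas) if betas else [],
            "se": np.concatenate(ses) if ses else [],
            "t_stat": np.concatenate(tstats) if tstats else [],
            "p_value": np.concatenate(pvals) if pvals else [],
        }
    )
    table["q_value"] = _bh(table, bh_scope)
    return QTLResultTable(
        table,
        covariate_ids=list(X.covariate_ids),
        n=n,
        df=df,
    )


def _bh(table: pd.DataFrame, bh_scope: str) -> np.ndarray:
    q = np.full(len(table), np.nan)
    if len(table) == 0:
        return q
    if bh_scope == "global":
        groups = [np.ones(len(table), dtype=bool)]
    elif bh_scope == "per_feature":
        groups = [
            (table["feature_id"] == f).to_numpy() for f in table["feature_id"].unique()
        ]
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    for mask in groups:
        finite = mask & np.isfinite(table["p_value"].to_numpy())
        if finite.any():
            q[finite] = multipletests(table.loc[finite, "p_value"], method="fdr_bh")[1]
    return q


def call_significant(result: QTLResultTable, fdr: float = 0.05) -> QTLResultTable:
    """Subset to rows passing the BH threshold (q_value <= fdr)."""
    sub = result.table[result.table["q_value"] <= fdr].copy()
    return QTLResultTable(sub, result.covariate_ids, result.n, result.df)


def write_qtl_table(result: QTLResultTable, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_qtl_table(path) -> QTLResultTable:
    table = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "snp_id": str})
    return QTLResultTable(table)
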