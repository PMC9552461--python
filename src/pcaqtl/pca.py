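"""PCA-based hidden covariate inference.

Two variants are supported, mirroring how PCA is used for confounder
correction in QTL mapping:

* ``pca_direct`` — run PCA on the (transformed) phenotype matrix itself,
  then drop any known covariate that the top PCs already capture well
  (unadjusted R^2 at or above a threshold, default 0.9).
* ``pca_resid`` — regress the known covariates out of each phenotype
  feature first, run PCA on the residuals, and keep all known covariates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import CovariateMatrix, PhenotypeMatrix

DEFAULT_R2_THRESHOLD = 0.9


@dataclass
class PCAResult:
    """SVD-based PCA of a samples x features matrix.

    ``scores`` are the sample-space PCs (n x r), ``loadings`` the feature
    weights (p x r), ``sdev`` the component standard deviations
    (singular value / sqrt(n-1)), and ``pve`` the proportion of variance
    explained by each component (non-increasing, summing to 1 over the
    full rank).
    """

    scores: np.ndarray
    loadings: np.ndarray
    sdev: np.ndarray
    pve: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def truncate(self, K: int) -> "PCAResult":
        if not 1 <= K <= self.n_components:
            raise ValueError(f"K={K} out of range 1..{self.n_components}")
        return PCAResult(self.scores[:, :K], self.loadings[:, :K], self.sdev[:K], self.pve[:K])

    def scores_matrix(self, sample_ids, K: Optional[int] = None) -> CovariateMatrix:
        K = self.n_components if K is None else K
        return CovariateMatrix(
            self.scores[:, :K], sample_ids, [f"PC{i + 1}" for i in range(K)], role="inferred"
        )


def _standardize(vals: np.ndarray, center: bool, scale: bool) -> np.ndarray:
    out = vals.astype(float, copy=True)
    if center:
        out -= out.mean(axis=0)
    if scale:
        sd = vals.std(axis=0, ddof=1)
        if np.any(sd == 0):
            idx = int(np.nonzero(sd == 0)[0][0])
            raise ValueError(f"zero-variance feature at column {idx} cannot be scaled")
        out /= sd
    return out


def run_pca(Y: PhenotypeMatrix, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA of the phenotype matrix via SVD of the centered/scaled data.

    Centering is applied before scaling; scaling uses the ddof=1 standard
    deviation. The sign of each component is fixed so that its largest-
    magnitude loading is positive, making output reproducible across
    linear-algebra backends. At most min(n-1, p) components are returned.
    """
    M = _standardize(Y.values, center, scale)
    return _pca_of_matrix(M, max_rank=min(Y.n_samples - 1, Y.n_features))


def _pca_of_matrix(M: np.ndarray, max_rank: int) -> PCAResult:
    n = M.shape[0]
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    r = min(max_rank, len(s))
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(Vt[np.arange(r), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    scores = U * s
    sdev = s / np.sqrt(n - 1)
    total = float(np.sum(s**2))
    pve = (s**2) / total if total > 0 else np.zeros_like(s)
    return PCAResult(scores, Vt.T, sdev, pve)


def regress_out(Y: PhenotypeMatrix, X1: CovariateMatrix) -> PhenotypeMatrix:
    """Replace each phenotype feature by its OLS residual on [1, X1].

    With an empty covariate matrix this reduces to mean-centering.
    Collinear covariate columns are dropped with a warning before the fit.
    """
    vals = Y.values
    if X1.n_covariates == 0:
        resid = vals - vals.mean(axis=0)
    else:
        X = prune_collinear(np.column_stack([np.ones(Y.n_samples), X1.values]))
        Q, _ = np.linalg.qr(X)
        resid = vals - Q @ (Q.T @ vals)
    return PhenotypeMatrix(resid, Y.sample_ids, Y.feature_ids, Y.feature_coords)


def prune_collinear(X: np.ndarray, tol: float = 1e-10, warn: bool = True) -> np.ndarray:
    """Drop columns of X that are linearly dependent on earlier columns."""
    if X.shape[1] == 0:
        return X
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size else 0
    if rank == X.shape[1]:
        return X
    keep = np.sort(piv[:rank])
    if warn:
        warnings.warn(f"dropping {X.shape[1] - rank} collinear design column(s)")
    return X[:, keep]


@dataclass
class CovariateFilterResult:
    kept: CovariateMatrix
    dropped: list
    r2: pd.Series  # unadjusted R^2 of each known covariate on the inferred set


def filter_known_covariates(
    X1: CovariateMatrix,
    X_inferred: CovariateMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> CovariateFilterResult:
    """Drop known covariates already captured by the inferred covariates.

    Each known covariate is regressed (with intercept) on the full
    inferred set; covariates with unadjusted R^2 >= ``r2_threshold`` are
    dropped. Returns the retained matrix, the dropped ids, and the
    per-covariate R^2 report.
    """
    if X1.sample_ids != X_inferred.sample_ids:
        raise ValueError("covariate matrices are not sample-aligned")
    n = len(X1.sample_ids)
    if X1.n_covariates == 0:
        return CovariateFilterResult(X1, [], pd.Series(dtype=float))
    D = prune_collinear(
        np.column_stack([np.ones(n), X_inferred.values]), warn=False
    )
    Q, _ = np.linalg.qr(D)
    r2s = {}
    for j, cid in enumerate(X1.covariate_ids):
        y = X1.values[:, j]
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            raise ValueError(f"known covariate {cid!r} has zero variance")
        resid = y - Q @ (Q.T @ y)
        r2s[cid] = 1.0 - float(np.sum(resid**2)) / tss
    r2 = pd.Series(r2s)
    keep_mask = r2.values < r2_threshold
    kept = CovariateMatrix(
        X1.values[:, keep_mask],
        X1.sample_ids,
        [c for c, k in zip(X1.covariate_ids, keep_mask) if k],
        role=X1.role,
    )
    dropped = [c for c, k in zip(X1.covariate_ids, keep_mask) if not k]
    return CovariateFilterResult(kept, dropped, r2)


@dataclass
class InferenceResult:
    X_inferred: CovariateMatrix
    X1_used: CovariateMatrix
    pca: PCAResult
    filter_report: Optional[CovariateFilterResult] = None


def infer_covariates(
    Y: PhenotypeMatrix,
    X1: CovariateMatrix,
    variant: str = "pca_direct",
    K: int = 10,
    center: bool = True,
    scale: bool = True,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> InferenceResult:
    """Infer hidden covariates as top-K PCs under either PCA variant.

    ``pca_direct`` runs PCA on Y itself and then filters known covariates
    captured by the PCs; ``pca_resid`` residualizes Y on the known
    covariates first (re-centering and re-scaling the residuals before the
    SVD) and keeps the known covariates unfiltered.
    """
    max_k = min(Y.n_samples - 1, Y.n_features)
    if not 1 <= K <= max_k:
        raise ValueError(f"K={K} out of range 1..{max_k}")
    if Y.sample_ids != X1.sample_ids:
        raise ValueError("phenotypes and known covariates are not sample-aligned")

    if variant == "pca_direct":
        pca = run_pca(Y, center=center, scale=scale)
        X_inf = pca.scores_matrix(Y.sample_ids, K)
        report = filter_known_covariates(X1, X_inf, r2_threshold)
        return InferenceResult(X_inf, report.kept, pca, report)
    if variant == "pca_resid":
        resid = regress_out(Y, X1)
        pca = run_pca(resid, center=center, scale=scale)
        X_inf = pca.scores_matrix(Y.sample_ids, K)
        return InferenceResult(X_inf, X1, pca, None)
    raise ValueError(f"unknown variant {variant!r}")
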