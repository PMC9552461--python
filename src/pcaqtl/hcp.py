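"""Hidden Covariates with Prior (HCP), fit by block coordinate descent.

HCP infers K hidden components Z from a phenotype matrix Y (n x p,
centered and scaled upstream) while softly coupling them to the known
covariates X1 (n x K1). The objective is

    ||Y - Z B||_F^2 + lambda1 ||Z - X1 U||_F^2
                    + lambda2 ||B||_F^2 + lambda3 ||U||_F^2,

a penalized version of PCA's minimum-reconstruction-error loss. Each of
Z, B, U has a closed-form minimizer given the other two, so cyclic block
updates decrease the objective monotonically. Initialization is
deterministic (Z0 = top-K PC scores of Y), making fits bit-reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CovariateMatrix, PhenotypeMatrix
from .pca import _pca_of_matrix


@dataclass
class HCPFit:
    Z: np.ndarray  # n x K hidden components
    B: np.ndarray  # K x p feature coefficients
    U: np.ndarray  # K1 x K known-to-hidden coefficients
    lambdas: tuple
    objective_trace: np.ndarray
    iterations: int
    converged: bool

    def components(self, sample_ids) -> CovariateMatrix:
        K = self.Z.shape[1]
        return CovariateMatrix(
            self.Z, sample_ids, [f"HCP{i + 1}" for i in range(K)], role="inferred"
        )


def _objective(Y, X1, Z, B, U, l1, l2, l3) -> float:
    return (
        float(np.sum((Y - Z @ B) ** 2))
        + l1 * float(np.sum((Z - X1 @ U) ** 2))
        + l2 * float(np.sum(B**2))
        + l3 * float(np.sum(U**2))
    )


def _solve_psd(A, rhs):
    """Solve A x = rhs for symmetric PSD A, falling back to the
    pseudoinverse when the (unregularized) system is singular."""
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A) @ rhs


def _update_B(Y, Z, l2):
    K = Z.shape[1]
    return _solve_psd(Z.T @ Z + l2 * np.eye(K), Z.T @ Y)


def _update_U(X1, Z, l1, l3):
    K1 = X1.shape[1]
    return _solve_psd(l1 * (X1.T @ X1) + l3 * np.eye(K1), l1 * (X1.T @ Z))


def _update_Z(Y, X1, B, U, l1):
    K = B.shape[0]
    A = B @ B.T + l1 * np.eye(K)
    return _solve_psd(A, (Y @ B.T + l1 * (X1 @ U)).T).T


def fit_hcp(
    Y: PhenotypeMatrix,
    X1: CovariateMatrix,
    K: int,
    lambdas: tuple = (1.0, 1.0, 1.0),
    tol: float = 1e-6,
    max_iter: int = 100,
) -> HCPFit:
    """Fit HCP by cyclic closed-form block updates (order Z -> B -> U).

    Stops when the relative objective decrease over one full sweep falls
    below ``tol`` or after ``max_iter`` sweeps. ``lambdas`` = (coupling to
    X1, ridge on B, ridge on U); all must be non-negative.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    l1, l2, l3 = (float(v) for v in lambdas)
    if min(l1, l2, l3) < 0:
        raise ValueError("lambdas must be non-negative")
    if X1.n_covariates == 0:
        raise ValueError("HCP requires a nonempty known covariate matrix")
    if Y.sample_ids != X1.sample_ids:
        raise ValueError("phenotypes and covariates are not sample-aligned")
    Ym, X1m = Y.values, X1.values
    if l1 == 0 and K > min(Ym.shape):
        warnings.warn("lambda1 = 0 with K above rank(Y): scale of Z is unidentifiable")

    # deterministic init: top-K PC scores of Y as provided
    pca = _pca_of_matrix(Ym - Ym.mean(axis=0), max_rank=min(Ym.shape[0] - 1, Ym.shape[1]))
    r = pca.scores.shape[1]
    Z = np.zeros((Ym.shape[0], K))
    Z[:, : min(K, r)] = pca.scores[:, : min(K, r)]
    B = _update_B(Ym, Z, l2)
    U = _update_U(X1m, Z, l1, l3)

    trace = [_objective(Ym, X1m, Z, B, U, l1, l2, l3)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Z = _update_Z(Ym, X1m, B, U, l1)
        B = _update_B(Ym, Z, l2)
        U = _update_U(X1m, Z, l1, l3)
        obj = _objective(Ym, X1m, Z, B, U, l1, l2, l3)
        if not np.isfinite(obj):
            raise FloatingPointError("HCP objective became non-finite")
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return HCPFit(Z, B, U, (l1, l2, l3), np.asarray(trace), it, converged)
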