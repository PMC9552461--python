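"""Factor-redundancy and factor-vs-PC diagnostics.

Inferred factors (e.g. from an external factor-analysis tool) are not
guaranteed to be uncorrelated; heavily redundant factors waste covariate
degrees of freedom and can miss major variance components. Two checks
are provided:

* correlation clustering — group factors so that within a cluster every
  pairwise correlation exceeds a threshold in absolute value (complete-
  linkage hierarchical clustering at distance 1 - |cor|); the number of
  clusters counts the distinct factors.
* factor-to-PC matching — pair each factor with a top PC by greedily
  taking the largest remaining |cor|, then summarize the reordered
  |correlation| matrix by its diagonal and off-diagonal means. A diagonal
  mean near 1 with an off-diagonal mean near 0 indicates the factors are
  essentially a relabeling of the PCs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .containers import CovariateMatrix


@dataclass
class ClusterReport:
    threshold: float
    num_factors: int
    num_clusters: int
    labels: np.ndarray  # cluster id per factor, 1-based


@dataclass
class MatchReport:
    permutation: np.ndarray  # factor index i is paired with PC column permutation[i]
    pair_abs_cor: np.ndarray
    diag_mean: float
    offdiag_mean: float
    diag_se: float
    offdiag_se: float
    reordered_abs_cor: np.ndarray  # rows factors, columns PCs in matched order


def _abs_cor(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    if np.any(A.std(axis=0) == 0) or (B is not None and np.any(B.std(axis=0) == 0)):
        raise ValueError("zero-variance column: correlation undefined")
    if B is None:
        return np.abs(np.corrcoef(A, rowvar=False))
    ka = A.shape[1]
    full = np.corrcoef(np.column_stack([A, B]), rowvar=False)
    return np.abs(full[:ka, ka:])


def count_factor_clusters(factors: CovariateMatrix, threshold: float = 0.9) -> ClusterReport:
    """Count distinct factors via complete-linkage correlation clustering.

    Factors land in the same cluster only if all their pairwise |cor|
    values are strictly above ``threshold`` (the tree is cut just below
    height 1 - threshold).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    K = factors.n_covariates
    if K < 1:
        raise ValueError("need at least one factor")
    if K == 1:
        return ClusterReport(threshold, 1, 1, np.ones(1, dtype=int))
    dist = 1.0 - _abs_cor(factors.values)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    tree = linkage(squareform(dist, checks=False), method="complete")
    # strict cut: merges at exactly 1 - threshold stay separate
    cut = np.nextafter(1.0 - threshold, -1.0)
    labels = fcluster(tree, t=cut, criterion="distance")
    return ClusterReport(threshold, K, int(labels.max()), labels)


def match_factors_to_pcs(
    factors: CovariateMatrix,
    pcs: CovariateMatrix,
    method: str = "greedy",
) -> MatchReport:
    """Match factors to top PCs and summarize the |correlation| matrix.

    ``greedy`` repeatedly pairs the (factor, PC) with the largest
    remaining |cor|; ``optimal`` solves the assignment maximizing the
    total |cor|. PCs beyond the number of factors are truncated; fewer
    PCs than factors is an error.
    """
    K = factors.n_covariates
    if pcs.n_covariates < K:
        raise ValueError("fewer PCs than factors")
    if factors.sample_ids != pcs.sample_ids:
        raise ValueError("inputs are not sample-aligned")
    P = pcs.values[:, :K]
    C = _abs_cor(factors.values, P)

    perm = np.empty(K, dtype=int)
    if method == "greedy":
        work = C.copy()
        for _ in range(K):
            i, j = np.unravel_index(np.argmax(work), work.shape)
            perm[i] = j
            work[i, :] = -1.0
            work[:, j] = -1.0
    elif method == "optimal":
        rows, cols = linear_sum_assignment(-C)
        perm[rows] = cols
    else:
        raise ValueError(f"unknown matching method {method!r}")

    reordered = C[:, perm]  # column j' = PC matched to factor j'
    diag = np.diag(reordered)
    off = reordered[~np.eye(K, dtype=bool)]
    diag_se = float(diag.std(ddof=1) / np.sqrt(K)) if K > 1 else 0.0
    off_se = float(off.std(ddof=1) / np.sqrt(off.size)) if off.size > 1 else 0.0
    return MatchReport(
        permutation=perm,
        pair_abs_cor=diag.copy(),
        diag_mean=float(diag.mean()),
        offdiag_mean=float(off.mean()) if off.size else 0.0,
        diag_se=diag_se,
        offdiag_se=off_se,
        reordered_abs_cor=reordered,
    )
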