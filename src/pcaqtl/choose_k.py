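"""Choosing the number of PCs: automatic elbow detection on the scree
plot, and the Buja-Eyuboglu (BE) permutation test.

The BE algorithm is a parallel-analysis procedure: it retains a PC only
if it explains more variance than the same-rank PC of column-permuted
data, i.e. more than expected by chance once inter-feature correlation is
destroyed. Selected components always form a prefix of the scree (the
scan stops at the first non-significant component), matching how top-K
PCs are consumed downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PhenotypeMatrix
from .pca import _pca_of_matrix, _standardize


@dataclass
class KSelection:
    method: str  # "elbow" or "be"
    K: int
    diagnostics: pd.DataFrame
    params: dict = field(default_factory=dict)
    seed: int | None = None


def elbow_select(pve: np.ndarray) -> KSelection:
    """Pick K at the scree-plot elbow.

    Each scree point (k, pve_k) is scored by its perpendicular distance to
    the chord joining the first and last points; K is the component with
    the largest distance (smallest index on ties). Requires a
    non-increasing PVE vector of length >= 3.
    """
    pve = np.asarray(pve, dtype=float)
    if pve.ndim != 1 or len(pve) < 3:
        raise ValueError("need a PVE vector of length >= 3")
    if np.any(pve < 0):
        raise ValueError("PVE entries must be non-negative")
    if np.any(np.diff(pve) > 1e-12):
        raise ValueError("PVE vector is not non-increasing; not a scree")
    r = len(pve)
    x = np.arange(1, r + 1, dtype=float)
    # perpendicular distance from (x_k, pve_k) to the chord (x_1,pve_1)-(x_r,pve_r)
    dx, dy = x[-1] - x[0], pve[-1] - pve[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (pve - pve[0])) / norm
    # smallest index among (floating-point) ties for the largest distance
    K = int(np.argmax(dist >= dist.max() - 1e-12)) + 1
    diagnostics = pd.DataFrame({"component": x.astype(int), "pve": pve, "distance": dist})
    return KSelection("elbow", K, diagnostics, params={})


def be_select(
    Y: PhenotypeMatrix,
    B: int = 20,
    alpha: float = 0.05,
    seed: int | None = None,
    center: bool = True,
    scale: bool = True,
) -> KSelection:
    """Choose K by the Buja-Eyuboglu permutation test.

    For each of B permutation rounds, every column of the (centered/
    scaled) phenotype matrix is permuted independently and the PVE profile
    of the permuted matrix recorded. Component k is significant when its
    observed PVE exceeds the (1 - alpha) empirical quantile (the ``higher``
    order statistic) of its B permuted counterparts; K is the length of
    the initial run of significant components.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if Y.n_samples < 3:
        raise ValueError("need at least 3 samples for the permutation test")

    M = _standardize(Y.values, center, scale)
    max_rank = min(Y.n_samples - 1, Y.n_features)
    observed = _pca_of_matrix(M, max_rank).pve
    r = len(observed)

    rng = np.random.default_rng(seed)
    perm_pve = np.empty((B, r))
    cols = np.arange(M.shape[1])
    for b in range(B):
        # independent permutation within each column via random sort keys
        keys = rng.random(M.shape).argsort(axis=0)
        P = M[keys, cols]
        perm_pve[b] = _pca_of_matrix(P, max_rank).pve[:r]

    quantiles = np.quantile(perm_pve, 1.0 - alpha, axis=0, method="higher")
    significant = observed > quantiles
    K = int(np.argmax(~significant)) if not significant.all() else r

    diagnostics = pd.DataFrame(
        {
            "component": np.arange(1, r + 1),
            "pve": observed,
            "perm_quantile": quantiles,
            "significant": significant,
        }
    )
    return KSelection("be", K, diagnostics, params={"B": B, "alpha": alpha}, seed=seed)
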