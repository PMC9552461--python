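"""Core in-memory containers shared across the package.

All containers store samples in rows.  Alignment across phenotype,
covariate, and genotype inputs is by sample identifier, with the
phenotype matrix's ordering taken as canonical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"duplicated {what}: {sorted(set(dupes))[:10]}")


@dataclass
class PhenotypeMatrix:
    """Fully processed molecular phenotype matrix, samples x features.

    Parameters
    ----------
    values : (n, p) float array
        Phenotype values; must be finite (loaders reject or impute NaN).
    sample_ids, feature_ids : sequences of str
        Unique identifiers for rows and columns.
    feature_coords : DataFrame, optional
        Indexed by feature id with columns ``chrom``, ``start``, ``end``
        (1-based, inclusive); used for cis-window SNP lookup.
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list
    feature_coords: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.feature_ids)} features"
            )
        if n < 2 or p < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_ids, "feature ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing values in phenotype matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids) -> "PhenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, values=self.values[idx], sample_ids=list(sample_ids))


@dataclass
class CovariateMatrix:
    """Covariate matrix, samples x covariates.

    ``role`` labels the matrix as measured covariates (``known``), the
    simulation ground truth (``hidden_truth``), or the output of a hidden
    variable inference method (``inferred``).  May have zero columns
    (e.g., no known covariates).
    """

    values: np.ndarray
    sample_ids: list
    covariate_ids: list
    role: str = "known"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.sample_ids), -1)
        self.sample_ids = list(self.sample_ids)
        self.covariate_ids = list(self.covariate_ids)
        n, k = self.values.shape
        if n != len(self.sample_ids) or k != len(self.covariate_ids):
            raise ValueError("covariate matrix shape inconsistent with ids")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.covariate_ids, "covariate ids")
        if self.role not in ("known", "hidden_truth", "inferred"):
            raise ValueError(f"unknown covariate role {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing values in covariate matrix")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.covariate_ids)

    def subset_samples(self, sample_ids) -> "CovariateMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, values=self.values[idx], sample_ids=list(sample_ids))

    @classmethod
    def empty(cls, sample_ids, role: str = "known") -> "CovariateMatrix":
        return cls(np.empty((len(sample_ids), 0)), list(sample_ids), [], role=role)


@dataclass
class GenotypeData:
    """Genotype dosages, samples x SNPs, with a per-feature cis-SNP map.

    Dosages count alternate alleles (0/1/2; fractional after mean
    imputation of missing genotypes).  ``cis_map`` maps a feature id to
    the ordered array of SNP column indices within its cis window.
    """

    dosages: np.ndarray
    sample_ids: list
    snp_ids: list
    snp_coords: pd.DataFrame  # index snp_id, columns chrom, pos (1-based)
    maf: np.ndarray
    cis_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.snp_ids = list(self.snp_ids)
        self.maf = np.asarray(self.maf, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape inconsistent with ids")
        _check_unique(self.snp_ids, "SNP ids")
        if self.maf.shape != (m,):
            raise ValueError("maf must have one entry per SNP")
        for feat, idx in self.cis_map.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= m):
                raise ValueError(f"cis_map for {feat!r} has out-of-range SNP indices")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, sample_ids) -> "GenotypeData":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, dosages=self.dosages[idx], sample_ids=list(sample_ids))


def align_samples(pheno: PhenotypeMatrix, *others):
    """Align covariate/genotype containers to the phenotype sample order.

    Keeps the intersection of sample ids, in phenotype order, and logs how
    many phenotype samples were dropped.  Returns ``(pheno, *others)``
    re-indexed consistently.
    """
    common = set(pheno.sample_ids)
    for o in others:
        common &= set(o.sample_ids)
    if not common:
        raise ValueError("no samples shared across inputs")
    order = [s for s in pheno.sample_ids if s in common]
    dropped = len(pheno.sample_ids) - len(order)
    if dropped:
        logger.info("align_samples: dropped %d phenotype samples without matches", dropped)
    out = [pheno.subset_samples(order)]
    out.extend(o.subset_samples(order) for o in others)
    return tuple(out)
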