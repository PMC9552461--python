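"""Readers/writers for phenotype, covariate, and genotype inputs, plus the
three standard phenotype transforms (center/scale, INT within feature, INT
within sample).

On-disk dialects
----------------
* Phenotype TSV: tab-delimited with a header row; the first column holds
  row identifiers. ``orientation`` states whether rows are samples or
  features.
* Phenotype BED: GTEx-style — ``#chr  start  end  feature_id`` followed by
  one column per sample; start is 0-based on disk and converted to 1-based
  internally.
* Covariate TSV: samples in rows, covariates in columns, first column is
  the sample id.
* Genotype TSV: SNPs in rows with columns ``snp_id  chrom  pos`` followed
  by one dosage column per sample. VCF input uses the GT field.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .containers import CovariateMatrix, GenotypeData, PhenotypeMatrix

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "center_scale", "int_within_feature", "int_within_sample")
DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_MAF_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(
    path,
    format: str = "tsv",
    orientation: str = "samples_by_features",
    impute_mean: bool = False,
) -> PhenotypeMatrix:
    """Load a phenotype matrix from TSV or GTEx-style BED.

    The returned matrix is always oriented samples x features regardless
    of the on-disk orientation. Missing cells are a hard error unless
    ``impute_mean`` is set, in which case they are replaced by the feature
    mean.
    """
    if format == "bed":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.shape[1] < 5:
            raise ValueError("BED phenotype file needs 4 coordinate columns plus samples")
        coord_cols = df.columns[:4]
        feature_ids = df[coord_cols[3]].astype(str).tolist()
        coords = pd.DataFrame(
            {
                "chrom": df[coord_cols[0]].astype(str).values,
                # BED start is 0-based half-open; store 1-based inclusive
                "start": df[coord_cols[1]].astype(int).values + 1,
                "end": df[coord_cols[2]].astype(int).values,
            },
            index=feature_ids,
        )
        sample_ids = [str(c) for c in df.columns[4:]]
        values = df.iloc[:, 4:].to_numpy(dtype=float).T  # samples x features
        return _finalize_phenotypes(values, sample_ids, feature_ids, coords, impute_mean)

    if format != "tsv":
        raise ValueError(f"unknown phenotype format {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        raise ValueError("duplicated column ids in phenotype TSV header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    return _finalize_phenotypes(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(f) for f in df.columns],
        None,
        impute_mean,
    )


def _finalize_phenotypes(values, sample_ids, feature_ids, coords, impute_mean):
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        if not impute_mean:
            raise ValueError("missing values in phenotype matrix (set impute_mean to impute)")
        col_means = np.nanmean(values, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = col_means[nan_c]
        logger.info("imputed %d missing phenotype cells with feature means", len(nan_r))
    return PhenotypeMatrix(values, sample_ids, feature_ids, coords)


def write_phenotypes(Y: PhenotypeMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        Y.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "bed":
        if Y.feature_coords is None:
            raise ValueError("BED output requires feature coordinates")
        coords = Y.feature_coords.loc[Y.feature_ids]
        out = pd.DataFrame(
            {
                "#chr": coords["chrom"].values,
                "start": coords["start"].values - 1,
                "end": coords["end"].values,
                "feature_id": Y.feature_ids,
            }
        )
        vals = pd.DataFrame(Y.values.T, columns=Y.sample_ids)
        pd.concat([out, vals], axis=1).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown phenotype format {format!r}")


# ---------------------------------------------------------------------------
# covariates


def read_covariates(path, role: str = "known") -> CovariateMatrix:
    """Load a samples x covariates TSV; warns about and drops constant columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    keep = np.std(vals, axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance covariates: {dropped}")
        df = df.loc[:, keep]
    return CovariateMatrix(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        role=role,
    )


def write_covariates(X: CovariateMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path,
    format: str = "vcf",
    cis_window: int = DEFAULT_CIS_WINDOW,
    feature_coords: Optional[pd.DataFrame] = None,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    samples: Optional[Sequence[str]] = None,
) -> GenotypeData:
    """Load genotype dosages from a VCF (GT field) or the genotype TSV dialect.

    Dosage is the alternate-allele count; missing genotypes are imputed to
    the per-SNP mean of observed dosages. SNPs with minor-allele frequency
    below ``maf_threshold`` (computed after imputation) are dropped, as are
    non-biallelic sites. When ``feature_coords`` is given, a cis map is
    built pairing each feature with the SNPs whose position lies within
    ``cis_window`` bp of the feature's start (inclusive).
    """
    if format == "vcf":
        sample_ids, snp_ids, chroms, poss, dosages = _read_vcf(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
        for col in ("snp_id", "chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"genotype TSV missing column {col!r}")
        snp_ids = df["snp_id"].tolist()
        chroms = df["chrom"].astype(str).tolist()
        poss = df["pos"].astype(int).tolist()
        sample_ids = [str(c) for c in df.columns[3:]]
        dosages = df.iloc[:, 3:].to_numpy(dtype=float).T  # samples x snps
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    if samples is not None:
        missing = sorted(set(samples) - set(sample_ids))
        if missing:
            raise ValueError(f"samples absent from genotype data: {missing}")

    dosages = np.asarray(dosages, dtype=float)
    # mean-impute missing entries per SNP
    if np.isnan(dosages).any():
        col_means = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_means[nan_c]

    alt_freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = maf >= maf_threshold
    if not keep.all():
        logger.info("dropping %d SNPs with MAF < %g", int((~keep).sum()), maf_threshold)
    dosages = dosages[:, keep]
    snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    chroms = [c for c, k in zip(chroms, keep) if k]
    poss = [p for p, k in zip(poss, keep) if k]
    maf = maf[keep]

    snp_coords = pd.DataFrame({"chrom": chroms, "pos": poss}, index=snp_ids)
    cis_map = {}
    if feature_coords is not None:
        cis_map = build_cis_map(snp_coords, feature_coords, cis_window)
    return GenotypeData(dosages, sample_ids, snp_ids, snp_coords, maf, cis_map)


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:  # biallelic only
            continue
        if v.ploidy != 2:
            raise ValueError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
        # with gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
    vcf.close()
    if not rows:
        raise ValueError("no biallelic variants found in VCF")
    dosages = np.vstack(rows).T  # samples x snps
    return sample_ids, snp_ids, chroms, poss, dosages


def build_cis_map(snp_coords: pd.DataFrame, feature_coords: pd.DataFrame, cis_window: int) -> dict:
    """Map each feature to SNP indices within +/- ``cis_window`` bp of its start."""
    cis_map = {}
    snp_chrom = snp_coords["chrom"].to_numpy()
    snp_pos = snp_coords["pos"].to_numpy()
    for feat, row in feature_coords.iterrows():
        mask = (snp_chrom == str(row["chrom"])) & (np.abs(snp_pos - int(row["start"])) <= cis_window)
        cis_map[feat] = np.nonzero(mask)[0]
    return cis_map


def write_genotypes(G: GenotypeData, path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.snp_coords["chrom"].values,
            "pos": G.snp_coords["pos"].values,
        }
    )
    vals = pd.DataFrame(G.dosages.T, columns=G.sample_ids)
    pd.concat([df, vals], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms


def _int_blom(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps ranks r (average rank for ties) to Phi^{-1}((r - 3/8)/(n + 1/4)).
    """
    r = rankdata(x, method="average")
    return ndtri((r - 0.375) / (len(x) + 0.25))


def transform(Y: PhenotypeMatrix, method: str = "center_scale") -> PhenotypeMatrix:
    """Apply one of the standard phenotype transforms.

    * ``center_scale``: each feature to mean 0, sd 1 (ddof=1).
    * ``int_within_feature``: inverse normal transform of each feature.
    * ``int_within_sample``: inverse normal transform of each sample (row).
    * ``none``: returned unchanged.
    """
    if method == "none":
        return Y
    vals = Y.values
    if method == "center_scale":
        sd = vals.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            names = [Y.feature_ids[i] for i in zero[:10]]
            raise ValueError(f"zero-variance features cannot be scaled: {names}")
        out = (vals - vals.mean(axis=0)) / sd
    elif method == "int_within_feature":
        out = np.apply_along_axis(_int_blom, 0, vals)
    elif method == "int_within_sample":
        out = np.apply_along_axis(_int_blom, 1, vals)
    else:
        raise ValueError(f"unknown transform {method!r}; choose from {TRANSFORMS}")
    return PhenotypeMatrix(out, Y.sample_ids, Y.feature_ids, Y.feature_coords)
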