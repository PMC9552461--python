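"""Scoring QTL results and inferred covariates against simulation truth.

Three families of metrics:

* AUPRC over (feature, SNP) pairs ranked by ascending p-value — the
  appropriate ranking metric when true pairs are a small minority.
* Power: the fraction of true pairs called significant under either a BH
  FDR threshold or a nominal p-value threshold.
* Concordance between the true hidden covariates and the inferred
  covariates: the mean adjusted R^2 of each true covariate regressed on
  the inferred set (adjusted R^2 score), the mean adjusted R^2 of each
  inferred covariate regressed on the true set (reverse score), and their
  average (concordance score).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .containers import CovariateMatrix
from .qtl import QTLResultTable

logger = logging.getLogger(__name__)


def _pair_labels(table: pd.DataFrame, truth) -> tuple[np.ndarray, np.ndarray]:
    truth_set = {(str(f), str(s)) for f, s in truth}
    tested = set(zip(table["feature_id"].astype(str), table["snp_id"].astype(str)))
    missing = truth_set - tested
    if missing:
        raise ValueError(f"{len(missing)} truth pairs were never tested, e.g. {sorted(missing)[:3]}")
    labels = np.fromiter(
        ((f, s) in truth_set for f, s in zip(table["feature_id"].astype(str), table["snp_id"].astype(str))),
        dtype=bool,
        count=len(table),
    )
    return labels, table["p_value"].to_numpy(dtype=float)


def auprc(result: QTLResultTable, truth) -> float:
    """Area under the precision-recall curve of the p-value ranking.

    Pairs are ranked by ascending p-value; the curve is traced over the
    distinct-threshold steps (tied p-values collapse into one step) and
    the area is the step-wise sum of precision at achieved recall.
    Rows with NA p-values are excluded (their count is logged).
    """
    labels, p = _pair_labels(result.table, truth)
    finite = np.isfinite(p)
    if (~finite).any():
        logger.info("auprc: excluding %d pairs with NA p-values", int((~finite).sum()))
    labels, p = labels[finite], p[finite]
    if labels.sum() == 0:
        raise ValueError("no true pairs among tested pairs")
    if labels.sum() == len(labels):
        raise ValueError("no negative pairs among tested pairs")
    return float(average_precision_score(labels, -p))


def power(result: QTLResultTable, truth, rule: dict | None = None) -> float:
    """Fraction of truth pairs called significant under the given rule.

    ``rule`` is ``{"bh_fdr": level}`` (default level 0.05, using the
    table's q-values) or ``{"nominal_p": alpha}``.
    """
    rule = dict(rule or {"bh_fdr": 0.05})
    if len(rule) != 1:
        raise ValueError("rule must be exactly one of bh_fdr / nominal_p")
    labels, p = _pair_labels(result.table, truth)
    if labels.sum() == 0:
        raise ValueError("no true pairs among tested pairs")
    if "bh_fdr" in rule:
        q = result.table["q_value"].to_numpy(dtype=float)
        sig = np.isfinite(q) & (q <= rule["bh_fdr"])
    elif "nominal_p" in rule:
        sig = np.isfinite(p) & (p <= rule["nominal_p"])
    else:
        raise ValueError(f"unknown power rule {rule!r}")
    return float(sig[labels].sum() / labels.sum())


def _adjusted_r2_columns(targets: np.ndarray, predictors: np.ndarray) -> np.ndarray:
    """Adjusted R^2 of each target column regressed (with intercept) on
    all predictor columns: 1 - (1-R^2)(N-1)/(N-k-1)."""
    N, k = predictors.shape
    if k >= N - 1:
        raise ValueError("adjusted R^2 undefined: #covariates >= #samples - 1")
    D = np.column_stack([np.ones(N), predictors])
    Q, _ = np.linalg.qr(D)
    resid = targets - Q @ (Q.T @ targets)
    tss = np.sum((targets - targets.mean(axis=0)) ** 2, axis=0)
    if np.any(tss == 0):
        raise ValueError("zero-variance target column in adjusted R^2")
    r2 = 1.0 - np.sum(resid**2, axis=0) / tss
    return 1.0 - (1.0 - r2) * (N - 1) / (N - k - 1)


@dataclass
class ConcordanceResult:
    adj_r2_score: float
    rev_adj_r2_score: float
    concordance: float
    adj_r2_per_true: np.ndarray
    adj_r2_per_inferred: np.ndarray


def concordance(true_hidden: CovariateMatrix, inferred: CovariateMatrix) -> ConcordanceResult:
    """Concordance between true hidden covariates and inferred covariates.

    Computes m adjusted R^2's (each true covariate on the inferred set)
    and n adjusted R^2's (each inferred covariate on the true set); the
    two scores are their means and the concordance score is the average
    of the two. Invariant to invertible linear maps of either set.
    """
    if true_hidden.sample_ids != inferred.sample_ids:
        raise ValueError("covariate matrices are not sample-aligned")
    m, n_inf = true_hidden.n_covariates, inferred.n_covariates
    if m < 1 or n_inf < 1:
        raise ValueError("need at least one column on each side")
    N = len(true_hidden.sample_ids)
    if N <= max(m, n_inf) + 1:
        raise ValueError("too few samples for the adjusted R^2 comparison")
    fwd = _adjusted_r2_columns(true_hidden.values, inferred.values)
    rev = _adjusted_r2_columns(inferred.values, true_hidden.values)
    a, r = float(fwd.mean()), float(rev.mean())
    return ConcordanceResult(a, r, (a + r) / 2.0, fwd, rev)


@dataclass
class EvalReport:
    """Bundle of all metrics for one (method, data set) evaluation."""

    auprc: float
    power: float
    power_rule: dict
    adj_r2_score: float | None = None
    rev_adj_r2_score: float | None = None
    concordance: float | None = None
    m_pairs: int = 0
    tested_pairs: int = 0
    metadata: dict = field(default_factory=dict)


def evaluate_run(
    result: QTLResultTable,
    truth,
    true_hidden: CovariateMatrix | None = None,
    inferred: CovariateMatrix | None = None,
    power_rule: dict | None = None,
) -> EvalReport:
    """Convenience wrapper computing AUPRC, power, and (when both
    covariate matrices are supplied) the concordance scores."""
    rule = dict(power_rule or {"bh_fdr": 0.05})
    report = EvalReport(
        auprc=auprc(result, truth),
        power=power(result, truth, rule),
        power_rule=rule,
        m_pairs=len(set(map(tuple, truth))),
        tested_pairs=len(result.table),
        metadata={"pr_rule": "stepwise precision at achieved recall, ties collapsed"},
    )
    if true_hidden is not None and inferred is not None and true_hidden.n_covariates > 0:
        c = concordance(true_hidden, inferred)
        report.adj_r2_score = c.adj_r2_score
        report.rev_adj_r2_score = c.rev_adj_r2_score
        report.concordance = c.concordance
    return report
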