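"""End-to-end orchestration: the recommended inference workflow
(transform -> PCA -> choose K -> filter known covariates -> merged
covariate table) and the simulation benchmark, both driven by a config
mapping (or YAML file) and recorded in a run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .choose_k import KSelection, be_select, elbow_select
from .containers import CovariateMatrix
from .io_preprocess import (
    read_covariates,
    read_phenotypes,
    transform,
    write_covariates,
)
from .pca import infer_covariates, run_pca
from .simulate import SimParams, benchmark_grid

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    k_chosen: int | None = None
    k_method: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text()) or {}
    return dict(config)


def run_inference(config):
    """Run the recommended covariate-inference workflow.

    Config keys: ``phenotypes`` (path), ``phenotype_format`` (tsv/bed),
    ``known_covariates`` (path, optional), ``transform`` (default
    center_scale), ``variant`` (pca_direct/pca_resid), ``k_policy``
    ({"fixed": k} | "elbow" | "be"), ``seed``, ``outdir``.

    Returns ``(X_inferred, X1_used, KSelection, RunManifest)`` and writes
    the merged covariate table ready for the QTL pass.
    """
    cfg = _load_config(config)
    outdir = Path(cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg.get("seed"))
    stage = "load"
    try:
        t0 = time.perf_counter()
        Y = read_phenotypes(
            cfg["phenotypes"],
            format=cfg.get("phenotype_format", "tsv"),
            orientation=cfg.get("orientation", "samples_by_features"),
        )
        manifest.input_digests["phenotypes"] = _digest(cfg["phenotypes"])
        if cfg.get("known_covariates"):
            X1 = read_covariates(cfg["known_covariates"])
            X1 = X1.subset_samples(Y.sample_ids)
            manifest.input_digests["known_covariates"] = _digest(cfg["known_covariates"])
        else:
            X1 = CovariateMatrix.empty(Y.sample_ids)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "transform"
        t0 = time.perf_counter()
        Yt = transform(Y, cfg.get("transform", "center_scale"))
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "choose_k"
        t0 = time.perf_counter()
        policy = cfg.get("k_policy", "be")
        if isinstance(policy, dict) and "fixed" in policy:
            K = int(policy["fixed"])
            ksel = KSelection("fixed", K, diagnostics=None, params=dict(policy))
        elif policy == "elbow":
            ksel = elbow_select(run_pca(Yt).pve)
            K = max(ksel.K, 1)
        elif policy == "be":
            ksel = be_select(
                Yt,
                B=int(cfg.get("be_B", 20)),
                alpha=float(cfg.get("be_alpha", 0.05)),
                seed=cfg.get("seed"),
            )
            K = max(ksel.K, 1)
        else:
            raise ValueError(f"unknown K policy {policy!r}")
        manifest.k_chosen, manifest.k_method = K, ksel.method
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "infer"
        t0 = time.perf_counter()
        res = infer_covariates(
            Yt, X1, variant=cfg.get("variant", "pca_direct"), K=K,
            r2_threshold=float(cfg.get("r2_threshold", 0.9)),
        )
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "write"
        merged = CovariateMatrix(
            np.column_stack([res.X1_used.values, res.X_inferred.values]),
            Y.sample_ids,
            res.X1_used.covariate_ids + res.X_inferred.covariate_ids,
        )
        cov_path = outdir / "covariates_merged.tsv"
        write_covariates(merged, cov_path)
        manifest.output_digests[str(cov_path)] = _digest(cov_path)
        if res.filter_report is not None:
            rep_path = outdir / "known_covariate_filter.tsv"
            res.filter_report.r2.rename("r2").to_csv(rep_path, sep="\t")
            manifest.output_digests[str(rep_path)] = _digest(rep_path)
        manifest.write(outdir / "manifest.json")
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        manifest.write(outdir / "manifest.json")
        raise
    return res.X_inferred, res.X1_used, ksel, manifest


def run_benchmark(config):
    """Run the simulation benchmark described by the config.

    Config keys: ``base`` (SimParams overrides), ``grid`` (axis -> level
    list), ``replicates``, ``methods``, ``seed``, ``k`` (int | "elbow" |
    "be" | null for true K), ``outdir``.
    """
    cfg = _load_config(config)
    outdir = Path(cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg.get("seed"))
    t0 = time.perf_counter()
    base = SimParams(**cfg.get("base", {}))
    table = benchmark_grid(
        base,
        cfg.get("grid", {}),
        replicates=int(cfg.get("replicates", 2)),
        methods=tuple(cfg.get("methods", ["ideal", "unadjusted", "pca_direct"])),
        seed=cfg.get("seed"),
        K=cfg.get("k"),
    )
    manifest.timings["benchmark"] = time.perf_counter() - t0
    out_path = outdir / "benchmark_results.tsv"
    table.to_csv(out_path, sep="\t", index=False)
    manifest.output_digests[str(out_path)] = _digest(out_path)
    manifest.write(outdir / "manifest.json")
    return table, manifest
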