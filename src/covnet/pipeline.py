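"""End-to-end pipeline: decomposition, both network estimators, modules, concepts.

``run_pipeline`` reproduces the four-network comparison: the network of the
original metabolite values and the network of the covariable-specific parts,
each estimated by soft-thresholded correlation (WGCNA-style) and/or by the
graphical lasso with StARS.  Metabolites discarded by the decomposition are
dropped from the covariable-specific networks only; the original-value
networks keep every metabolite.  All artifacts are TSV (plus GraphML for
thresholded networks) and a JSON manifest records every parameter, seed,
chosen power and penalty.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster, concepts, corrnet, ggm, io
from .decompose import adjust_nuisance, decompose
from .tables import DesignTable, SampleTable

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("covnet")


@dataclass
class RunConfig:
    """All pipeline parameters (defaults follow the small-study presets)."""

    target: str = "genotype"
    nuisance: list[str] = field(default_factory=list)
    alpha: float = 0.05
    selection: bool = True
    method: str = "both"  # corr | ggm | both
    gamma: int | None = None  # None: choose from (N, P) by the noise bound
    gamma_max: int = 12
    edge_fraction: float = 0.05
    n_lambda: int = 30
    lambda_min_ratio: float = 0.05
    stars_subsamples: int = 100
    stars_subsample_size: int | None = None
    stars_allowance: float = 0.05
    min_module_size: int = 3
    cut_height_quantile: float = 0.99
    seed: int = 0
    outdir: str = "covnet-out"

    def __post_init__(self) -> None:
        if self.method not in ("corr", "ggm", "both"):
            raise ValueError("method must be corr, ggm or both")
        if not 0 <= self.edge_fraction <= 1:
            raise ValueError("edge_fraction must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        # the output location does not affect the analysis identity
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:8]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def _analyze_corr(
    samples: SampleTable, config: RunConfig, tag: str, prefix: Path, manifest: dict
) -> dict:
    n, p = samples.n_samples, samples.n_metabolites
    gamma = config.gamma or corrnet.select_gamma(n, p, config.gamma_max)
    W = corrnet.intensity_matrix(samples, gamma)
    threshold, A = corrnet.top_fraction_edges(W, config.edge_fraction)
    D = cluster.dissimilarity(W)
    dend = cluster.average_linkage(D, node_ids=list(W.node_ids))
    modules = cluster.cut_modules(
        dend, D, config.min_module_size, config.cut_height_quantile
    )
    summary = concepts.summarize(W, modules)
    top = concepts.top_connected(A, k=15)
    io.write_matrix(W, prefix.with_name(prefix.name + "_corr_intensity.tsv"))
    io.write_edge_list(
        W, prefix.with_name(prefix.name + "_corr_edges.tsv"), adjacency=A
    )
    io.write_matrix(summary, prefix.with_name(prefix.name + "_corr_concepts.tsv"))
    io.write_matrix(
        pd.DataFrame(
            {
                "node": modules.node_ids,
                "module": modules.labels,
                "color": [modules.color(int(l)) for l in modules.labels],
            }
        ),
        prefix.with_name(prefix.name + "_corr_modules.tsv"),
    )
    io.write_matrix(top, prefix.with_name(prefix.name + "_corr_top_connected.tsv"))
    io.write_graphml(
        W, A, prefix.with_name(prefix.name + "_corr_network.graphml"), modules
    )
    manifest["networks"][tag]["corr"] = {
        "gamma": int(gamma),
        "edge_fraction": config.edge_fraction,
        "edge_threshold": float(threshold) if np.isfinite(threshold) else None,
        "n_nodes": p,
        "n_modules": len(modules.module_ids),
        "density": concepts.density(W),
    }
    return {"intensity": W, "adjacency": A, "modules": modules, "summary": summary}


def _analyze_ggm(
    samples: SampleTable, config: RunConfig, tag: str, prefix: Path, manifest: dict
) -> dict:
    n = samples.n_samples
    sub = config.stars_subsample_size or min(n - 1, int(np.floor(10 * np.sqrt(n))))
    stars = ggm.stars_select(
        samples,
        n_subsamples=config.stars_subsamples,
        subsample_size=sub,
        allowance=config.stars_allowance,
        seed=config.seed,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    W = stars.stability
    edges = stars.precision.edge_matrix().astype(int)
    A = corrnet.AdjacencyMatrix(list(W.node_ids), edges)
    D = cluster.dissimilarity(W)
    dend = cluster.average_linkage(D, node_ids=list(W.node_ids))
    modules = cluster.cut_modules(
        dend, D, config.min_module_size, config.cut_height_quantile
    )
    summary = concepts.summarize(W, modules)
    top = concepts.top_connected(A, k=15)
    io.write_matrix(W, prefix.with_name(prefix.name + "_ggm_stability.tsv"))
    io.write_edge_list(
        W, prefix.with_name(prefix.name + "_ggm_edges.tsv"), adjacency=A
    )
    io.write_matrix(
        pd.DataFrame(
            {
                "lambda": stars.lambda_grid,
                "instability": stars.instability,
                "monotone_instability": stars.monotone,
            }
        ),
        prefix.with_name(prefix.name + "_ggm_instability.tsv"),
    )
    io.write_matrix(summary, prefix.with_name(prefix.name + "_ggm_concepts.tsv"))
    io.write_matrix(
        pd.DataFrame(
            {
                "node": modules.node_ids,
                "module": modules.labels,
                "color": [modules.color(int(l)) for l in modules.labels],
            }
        ),
        prefix.with_name(prefix.name + "_ggm_modules.tsv"),
    )
    io.write_matrix(top, prefix.with_name(prefix.name + "_ggm_top_connected.tsv"))
    manifest["networks"][tag]["ggm"] = {
        "lambda_star": stars.lambda_star,
        "fallback": stars.fallback,
        "allowance": config.stars_allowance,
        "n_subsamples": config.stars_subsamples,
        "subsample_size": sub,
        "n_modules": len(modules.module_ids),
        "density": concepts.density(W),
    }
    return {
        "stability": W,
        "stars": stars,
        "adjacency": A,
        "modules": modules,
        "summary": summary,
    }


def run_pipeline(
    samples: SampleTable, design: DesignTable, config: RunConfig
) -> dict:
    """Run the full comparison and write all artifacts under ``config.outdir``.

    Returns a dictionary with the decomposition result and, per network
    ("original", "covariable") and method, the estimated objects.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = f"run-{config.hash()}-seed{config.seed}"
    prefix_base = outdir / run_id
    manifest: dict = {
        "run_id": run_id,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_samples": samples.n_samples,
        "n_metabolites": samples.n_metabolites,
        "target": design.target,
        "reference_coding": {
            c.name: {"kind": c.kind, "reference": c.reference, "levels": c.levels}
            if c.kind == "categorical"
            else {"kind": c.kind}
            for c in design.covariables
        },
        "networks": {"original": {}, "covariable": {}},
    }
    design = design.align_to(samples)
    if config.nuisance:
        nuisance = pd.concat(
            [design.indicator_columns(c) for c in config.nuisance], axis=1
        )
        samples = _stage("adjust-nuisance")(adjust_nuisance, samples, nuisance)
        manifest["nuisance"] = list(config.nuisance)

    deco = _stage("decompose")(
        decompose, samples, design, alpha=config.alpha, selection=config.selection
    )
    report = deco.report()
    report.to_csv(prefix_base.with_name(run_id + "_selection.tsv"), sep="\t", index=False)
    manifest["n_kept"] = len(deco.kept_ids)

    results: dict = {"decomposition": deco, "original": {}, "covariable": {}}
    datasets = {"original": samples}
    if deco.covariable_parts is not None:
        datasets["covariable"] = deco.covariable_parts
    else:
        manifest["networks"]["covariable"]["skipped"] = (
            "fewer than 2 metabolites kept"
        )
    for tag, table in datasets.items():
        prefix = outdir / f"{run_id}_{tag}"
        if config.method in ("corr", "both"):
            results[tag]["corr"] = _stage(f"{tag}-corr")(
                _analyze_corr, table, config, tag, prefix, manifest
            )
        if config.method in ("ggm", "both"):
            results[tag]["ggm"] = _stage(f"{tag}-ggm")(
                _analyze_ggm, table, config, tag, prefix, manifest
            )
    with open(outdir / f"{run_id}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
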