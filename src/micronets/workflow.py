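"""End-to-end pipelines: construct, analyze, compare, and artifact output.

``construct_network`` strings preprocessing, association estimation,
sparsification and the adjacency transform together according to a
:class:`~micronets.config.WorkflowConfig`; ``construct_and_analyze``
adds the network characterization.  ``run_workflow`` is the file-based
entry point used by the command-line interface: it writes edge lists,
GraphML, JSON summaries and a log of all resolved parameters.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mio
from .associations import (NbhdConfig, SparccConfig, correlate,
                           neighborhood_select, proportionality_rho, sparcc)
from .config import WorkflowConfig
from .containers import (AdjacencyBundle, AssociationMatrix, CountMatrix,
                         GroupDesign, NormalizedMatrix)
from .netanalysis import NetworkProperties, analyze_network
from .netbuild import (BootstrapSpec, soft_threshold_adjacency, sparsify,
                       to_adjacency)
from .preprocess import filter_counts, normalize, replace_zeros
from .samplenet import knn_sparsify, sample_dissimilarity, scale_dissimilarity

__all__ = ["WorkflowConfig", "estimate_association", "construct_network",
           "construct_and_analyze", "build_sample_network", "run_workflow"]


def _normalized_input(counts: CountMatrix, cfg: WorkflowConfig):
    """Zero replacement + normalization for correlation-type measures."""
    if cfg.zero_method is not None:
        simplex = replace_zeros(counts, cfg.zero_method, **cfg.zero_params)
    else:
        simplex = None
    norm_method = cfg.norm_method
    if norm_method is None or norm_method == "TSS":
        if simplex is not None:
            return simplex
        return normalize(counts, "TSS")
    if norm_method == "clr":
        base = simplex.values if simplex is not None else counts.values
        from .preprocess import clr_transform
        return NormalizedMatrix(clr_transform(base), list(counts.sample_ids),
                                list(counts.taxon_ids), scale="clr-log",
                                method="clr",
                                zero_method=cfg.zero_method or "none")
    # count-scale normalizations operate on the raw counts
    return normalize(counts, norm_method, seed=cfg.seed, **cfg.norm_params)


def estimate_association(counts: CountMatrix,
                         cfg: WorkflowConfig) -> AssociationMatrix:
    measure = cfg.measure
    if measure in ("pearson", "spearman", "bicor"):
        norm = _normalized_input(counts, cfg)
        return correlate(norm, measure)
    if measure == "sparcc":
        sc = SparccConfig(seed=cfg.seed, **cfg.measure_params)
        return sparcc(counts, sc)
    if measure == "rho":
        simplex = replace_zeros(counts, cfg.zero_method or "multiplicative",
                                **cfg.zero_params)
        return proportionality_rho(simplex)
    if measure == "nbhd_partial":
        simplex = replace_zeros(counts, cfg.zero_method or "multiplicative",
                                **cfg.zero_params)
        from .preprocess import clr_transform
        clr = NormalizedMatrix(clr_transform(simplex.values),
                               list(counts.sample_ids),
                               list(counts.taxon_ids), scale="clr-log",
                               method="clr")
        nc = NbhdConfig(seed=cfg.seed, **cfg.measure_params)
        return neighborhood_select(clr, nc)
    raise ValueError(f"unknown measure {cfg.measure!r}")


def construct_network(
    counts: Optional[CountMatrix],
    cfg: Optional[WorkflowConfig] = None,
    assoc: Optional[AssociationMatrix] = None,
) -> tuple[AdjacencyBundle, AssociationMatrix]:
    """Counts (or a precomputed association matrix) to adjacency bundle."""
    cfg = cfg or WorkflowConfig()
    if assoc is None:
        if counts is None:
            raise ValueError("either counts or an association matrix is "
                             "required")
        if cfg.filter is not None:
            counts = filter_counts(counts, cfg.filter)
        assoc = estimate_association(counts, cfg)

    if cfg.sparsify_method == "soft":
        beta = cfg.soft_power or 6.0
        bundle = soft_threshold_adjacency(
            assoc, beta, sign_mode=cfg.sparsify_params.get("sign_mode",
                                                           "unsigned"))
        return bundle, assoc

    extra = {}
    if cfg.sparsify_method == "bootstrap":
        if counts is None:
            raise ValueError("bootstrap sparsification needs counts")
        sub_cfg = cfg

        def est(values: np.ndarray) -> np.ndarray:
            cm = CountMatrix(values,
                             [f"b{i}" for i in range(values.shape[0])],
                             list(assoc.taxon_ids))
            return estimate_association(cm, sub_cfg).values

        extra = dict(counts=counts, estimator=est,
                     bootstrap=BootstrapSpec(
                         reps=cfg.sparsify_params.get("reps", 999),
                         seed=cfg.seed, alpha=cfg.alpha,
                         adjust=cfg.adjust))
    sparse = sparsify(assoc, method=cfg.sparsify_method,
                      threshold=cfg.threshold, alpha=cfg.alpha,
                      adjust=cfg.adjust, **extra)
    bundle = to_adjacency(sparse, diss_mode=cfg.diss_mode,
                          weighted=cfg.weighted,
                          include_negatives=cfg.include_negatives)
    return bundle, assoc


def construct_and_analyze(counts: CountMatrix,
                          cfg: Optional[WorkflowConfig] = None,
                          include_betweenness: bool = True
                          ) -> NetworkProperties:
    cfg = cfg or WorkflowConfig()
    bundle, _ = construct_network(counts, cfg)
    return analyze_network(bundle, weighted=cfg.weighted,
                           cluster_method=cfg.cluster_method,
                           cluster_params=cfg.cluster_params,
                           hub_measures=cfg.hub_measures,
                           hub_method=cfg.hub_method, hub_q=cfg.hub_q,
                           include_betweenness=include_betweenness)


def build_sample_network(counts: CountMatrix,
                         cfg: Optional[WorkflowConfig] = None
                         ) -> AdjacencyBundle:
    """Sample dissimilarity network: zero handling, dissimilarity,
    scaling to [0, 1], kNN sparsification."""
    cfg = cfg or WorkflowConfig()
    if cfg.filter is not None:
        counts = filter_counts(counts, cfg.filter)
    if cfg.zero_method is not None:
        norm = replace_zeros(counts, cfg.zero_method, **cfg.zero_params)
    else:
        norm = normalize(counts, "TSS")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = sample_dissimilarity(norm, cfg.dissimilarity)
    d = scale_dissimilarity(d)
    return knn_sparsify(d, cfg.knn_k)


def run_workflow(cfg: WorkflowConfig, counts: CountMatrix, outdir,
                 mode: str = "construct",
                 design: Optional[GroupDesign] = None) -> dict:
    """Execute one workflow stage and write its artifacts.

    Modes: ``construct`` (single network: edge list, GraphML, analysis
    JSON), ``compare`` (two-group permutation comparison JSON + text
    table), ``diffnet`` (differential network edge list + JSON),
    ``samplenet`` (sample network artifacts).  A log of resolved
    parameters and seeds is always written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"mode": mode, "config": cfg.to_dict()}
    log: list[str] = [f"mode={mode}", f"seed={cfg.seed}"]
    try:
        if mode == "construct":
            bundle, assoc = construct_network(counts, cfg)
            props = analyze_network(bundle, weighted=cfg.weighted,
                                    cluster_method=cfg.cluster_method,
                                    cluster_params=cfg.cluster_params,
                                    hub_measures=cfg.hub_measures,
                                    hub_method=cfg.hub_method,
                                    hub_q=cfg.hub_q)
            mio.write_edge_list(bundle, outdir / "edges.tsv")
            mio.write_graphml(bundle, outdir / "network.graphml")
            mio.write_association(assoc, outdir / "association.tsv")
            mio.write_json(props.to_dict(), outdir / "analysis.json")
            artifacts["n_edges"] = bundle.n_edges
            log.append(f"edges={bundle.n_edges}")
        elif mode == "samplenet":
            bundle = build_sample_network(counts, cfg)
            props = analyze_network(
                bundle, weighted=True,
                cluster_method="hierarchical",
                cluster_params={"k": cfg.cluster_params.get("k", 3),
                                "linkage": "average"},
                hub_measures=cfg.hub_measures, hub_method=cfg.hub_method,
                hub_q=cfg.hub_q)
            mio.write_edge_list(bundle, outdir / "sample_edges.tsv")
            mio.write_graphml(bundle, outdir / "sample_network.graphml")
            mio.write_json(props.to_dict(),
                           outdir / "sample_analysis.json")
            artifacts["n_edges"] = bundle.n_edges
        elif mode == "compare":
            if design is None:
                raise ValueError("compare mode needs a group design")
            from .netcompare import permutation_compare
            res = permutation_compare(counts, design, cfg,
                                      n_perm=cfg.n_perm, seed=cfg.seed,
                                      alpha=cfg.compare_alpha,
                                      adjust=cfg.compare_adjust)
            mio.write_json(res.to_dict(), outdir / "comparison.json")
            (outdir / "comparison.txt").write_text(res.summary_table()
                                                   + "\n")
            artifacts["comparison"] = "comparison.json"
        elif mode == "diffnet":
            if design is None:
                raise ValueError("diffnet mode needs a group design")
            from .diffassoc import differential_network, fisher_z_test, \
                permutation_diff_test
            sub1 = CountMatrix(counts.values[design.mask1],
                               [s for s, m in zip(counts.sample_ids,
                                                  design.mask1) if m],
                               list(counts.taxon_ids))
            sub2 = CountMatrix(counts.values[design.mask2],
                               [s for s, m in zip(counts.sample_ids,
                                                  design.mask2) if m],
                               list(counts.taxon_ids))
            if cfg.measure in ("pearson", "spearman", "bicor", "sparcc"):
                a1 = estimate_association(sub1, cfg)
                a2 = estimate_association(sub2, cfg)
                res = fisher_z_test(a1, a2, adjust=cfg.compare_adjust)
            else:
                res = permutation_diff_test(
                    counts, design,
                    lambda cm: estimate_association(cm, cfg),
                    n_perm=cfg.n_perm, seed=cfg.seed,
                    adjust=cfg.compare_adjust)
            net = differential_network(res, alpha=cfg.compare_alpha)
            mio.write_json(
                {"alpha": net.alpha, "n_edges": net.n_edges,
                 "edges": [
                     {"taxon_a": net.taxon_ids[i],
                      "taxon_b": net.taxon_ids[j],
                      "weight": float(net.weights[i, j]),
                      "pvalue": float(res.adjusted[i, j])}
                     for i, j in zip(*np.nonzero(np.triu(net.weights, 1)))
                 ]},
                outdir / "diffnet.json")
            artifacts["n_edges"] = net.n_edges
        else:
            raise ValueError(f"unknown workflow mode {mode!r}")
    except Exception as exc:  # partial artifacts retained
        log.append(f"FAILED stage={mode}: {exc}")
        (outdir / "workflow.log").write_text("\n".join(log) + "\n")
        raise
    log.append("status=ok")
    (outdir / "workflow.log").write_text("\n".join(log) + "\n")
    mio.write_json(artifacts, outdir / "run.json")
    return artifacts
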