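"""Quantitative comparison of two networks.

The group-difference machinery follows the permutation paradigm: the
observed difference of a property between the two group networks is
referred to the distribution obtained by shuffling the group labels and
re-running the identical construction + analysis pipeline.  Similarity
of most-central-node sets is assessed by Jaccard's index against a
hypergeometric null with fixed set sizes; similarity of clusterings by
the adjusted Rand index with a label-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from .containers import CountMatrix, GroupDesign
from .netanalysis import GLOBAL_METRIC_NAMES, NetworkProperties
from .netbuild import adjust_pvalues

__all__ = [
    "JaccardResult",
    "RandResult",
    "ComparisonResult",
    "permutation_compare",
    "jaccard_test",
    "adjusted_rand_test",
    "most_central_set",
]

CENTRALITY_MEASURES = ("degree", "betweenness", "closeness", "eigenvector")


@dataclass
class JaccardResult:
    j: float
    n1_set: int
    n2_set: int
    N: int
    p_le: float
    p_ge: float


@dataclass
class RandResult:
    ari: float
    p: float
    n_perm: int


@dataclass
class ComparisonResult:
    node_ids: list[str]
    centrality_obs1: dict[str, np.ndarray]
    centrality_obs2: dict[str, np.ndarray]
    centrality_diff: dict[str, np.ndarray]
    centrality_pvalues: dict[str, np.ndarray]
    centrality_adjusted: dict[str, np.ndarray]
    global_obs1: dict[str, float]
    global_obs2: dict[str, float]
    global_diff: dict[str, float]
    global_pvalues: dict[str, float]
    jaccard: dict[str, JaccardResult]
    rand: Optional[RandResult]
    n_perm: int
    seed: Optional[int]
    group_names: tuple[str, str] = ("1", "2")

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_names),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "centralities": {
                m: [
                    {"id": nid,
                     "group1": float(self.centrality_obs1[m][i]),
                     "group2": float(self.centrality_obs2[m][i]),
                     "abs_diff": float(abs(self.centrality_diff[m][i])),
                     "pvalue": float(self.centrality_pvalues[m][i]),
                     "adjusted_pvalue": float(self.centrality_adjusted[m][i])}
                    for i, nid in enumerate(self.node_ids)
                ]
                for m in self.centrality_diff
            },
            "global": {
                g: {"group1": float(self.global_obs1[g]),
                    "group2": float(self.global_obs2[g]),
                    "abs_diff": float(abs(self.global_diff[g])),
                    "pvalue": float(self.global_pvalues[g])}
                for g in self.global_diff
            },
            "jaccard": {k: vars(v) for k, v in self.jaccard.items()},
            "rand": (vars(self.rand) if self.rand is not None else None),
        }

    def summary_table(self) -> str:
        """Plain-text table: metric, group values, abs. difference, p-value."""
        g1, g2 = self.group_names
        lines = [f"{'metric':<28}{g1:>12}{g2:>12}{'abs.diff':>12}"
                 f"{'p-value':>12}"]
        for g in self.global_diff:
            lines.append(
                f"{g:<28}{self.global_obs1[g]:>12.3f}"
                f"{self.global_obs2[g]:>12.3f}"
                f"{abs(self.global_diff[g]):>12.3f}"
                f"{self.global_pvalues[g]:>12.5f}")
        return "\n".join(lines)


def most_central_set(props: NetworkProperties, measure: str,
                     q: float = 0.75) -> set[str]:
    """Nodes above the empirical q-quantile of a normalized centrality."""
    vals = props.centralities.normalized(measure)
    thr = np.quantile(vals, q)
    return {nid for nid, v in zip(props.centralities.node_ids, vals)
            if v > thr}


def jaccard_test(setA: Sequence[str], setB: Sequence[str],
                 N: int) -> JaccardResult:
    """Jaccard index of two node sets with a hypergeometric random null.

    The null fixes the set sizes and draws both sets uniformly from a
    universe of N nodes; the intersection size is then hypergeometric
    and P(J <= j) / P(J >= j) sum its pmf on the respective (inclusive)
    side of the observed index.
    """
    A, B = set(setA), set(setB)
    if N < len(A | B):
        raise ValueError("universe size N smaller than |A union B|")
    a, b = len(A), len(B)
    if a == 0 and b == 0:
        warnings.warn("both sets empty; Jaccard index defined as 1",
                      RuntimeWarning)
        return JaccardResult(1.0, 0, 0, N, 1.0, 1.0)
    inter = len(A & B)
    j = inter / len(A | B)
    x_lo = max(0, a + b - N)
    x_hi = min(a, b)
    xs = np.arange(x_lo, x_hi + 1)
    pmf = hypergeom(N, a, b).pmf(xs)
    jx = xs / (a + b - xs)
    p_le = float(pmf[jx <= j + 1e-12].sum())
    p_ge = float(pmf[jx >= j - 1e-12].sum())
    return JaccardResult(float(j), a, b, N, min(p_le, 1.0), min(p_ge, 1.0))


def adjusted_rand_test(labelsA: Sequence[int], labelsB: Sequence[int],
                       n_perm: int = 1000,
                       seed: Optional[int] = None) -> RandResult:
    """Adjusted Rand index with a permutation test against random agreement.

    The second labeling is permuted uniformly; the two-sided p-value
    uses |ARI| with the pseudo-count convention (never exactly zero).
    """
    labelsA = np.asarray(labelsA)
    labelsB = np.asarray(labelsB)
    if labelsA.shape != labelsB.shape:
        raise ValueError("label vectors must have equal length")
    if len(set(labelsA)) == 1 and len(set(labelsB)) == 1:
        warnings.warn("single cluster in both partitions; ARI undefined, "
                      "returned as 1", RuntimeWarning)
        return RandResult(1.0, 1.0, n_perm)
    ari = float(adjusted_rand_score(labelsA, labelsB))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labelsB)
        if abs(adjusted_rand_score(labelsA, perm)) >= abs(ari) - 1e-12:
            count += 1
    return RandResult(ari, (count + 1) / (n_perm + 1), n_perm)


def _collect(props: NetworkProperties, measures: Sequence[str],
             metrics: Sequence[str]) -> tuple[dict, dict]:
    cents = {m: props.centralities.normalized(m).copy() for m in measures}
    glob = {g: float(getattr(props.global_metrics, g)) for g in metrics}
    return cents, glob


def permutation_compare(
    counts: CountMatrix,
    design: GroupDesign,
    config=None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    adjust: str = "adaptiveBH",
    centrality_measures: Sequence[str] = CENTRALITY_MEASURES,
    metrics: Sequence[str] = GLOBAL_METRIC_NAMES,
    jaccard_q: float = 0.75,
    rand_n_perm: int = 1000,
) -> ComparisonResult:
    """Permutation test of network-property differences between two groups.

    The count matrix is split by the design; the full construction +
    analysis pipeline (``config``, a :class:`micronets.config.
    WorkflowConfig`) runs on each subset.  For each of ``n_perm``
    label shuffles preserving the group sizes, both networks are
    re-estimated with the identical configuration and the property
    differences recorded; two-sided p-values use the pseudo-count
    convention (b+1)/(m+1).  Node-wise centrality p-values are
    multiplicity-adjusted (default adaptive Benjamini-Hochberg).
    """
    from .workflow import WorkflowConfig, construct_and_analyze

    if config is None:
        config = WorkflowConfig()
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse permutation p-value "
                      "resolution", RuntimeWarning)

    # taxa filtering must happen once, on the joint matrix, so both group
    # networks share a node set
    from .preprocess import filter_counts
    if config.filter is not None:
        counts = filter_counts(counts, config.filter)
    cfg = config.without_filter()

    X = counts.values
    labels1 = np.nonzero(design.mask1)[0]
    labels2 = np.nonzero(design.mask2)[0]

    def run(idx: np.ndarray) -> NetworkProperties:
        sub = CountMatrix(X[idx],
                          [counts.sample_ids[i] for i in idx],
                          list(counts.taxon_ids))
        return construct_and_analyze(
            sub, cfg, include_betweenness="betweenness" in
            centrality_measures)

    props1 = run(labels1)
    props2 = run(labels2)
    c1, g1 = _collect(props1, centrality_measures, metrics)
    c2, g2 = _collect(props2, centrality_measures, metrics)
    cdiff = {m: c1[m] - c2[m] for m in centrality_measures}
    gdiff = {g: g1[g] - g2[g] for g in metrics}

    n = counts.n_samples
    n1 = len(labels1)
    rng = np.random.default_rng(seed)
    c_exceed = {m: np.zeros(counts.n_taxa) for m in centrality_measures}
    g_exceed = {g: 0 for g in metrics}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx1, idx2 = perm[:n1], perm[n1:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pp1 = run(idx1)
            pp2 = run(idx2)
        pc1, pg1 = _collect(pp1, centrality_measures, metrics)
        pc2, pg2 = _collect(pp2, centrality_measures, metrics)
        for m in centrality_measures:
            c_exceed[m] += (np.abs(pc1[m] - pc2[m]) >=
                            np.abs(cdiff[m]) - 1e-12)
        for g in metrics:
            if abs(pg1[g] - pg2[g]) >= abs(gdiff[g]) - 1e-12:
                g_exceed[g] += 1

    c_p = {m: (c_exceed[m] + 1.0) / (n_perm + 1.0)
           for m in centrality_measures}
    c_adj = {m: adjust_pvalues(c_p[m], adjust) for m in centrality_measures}
    g_p = {g: (g_exceed[g] + 1.0) / (n_perm + 1.0) for g in metrics}

    # Jaccard similarity of most-central sets and hub sets
    present = (props1.centralities.degree > 0) | \
        (props2.centralities.degree > 0)
    universe = max(int(present.sum()), 1)
    jac: dict[str, JaccardResult] = {}
    for m in centrality_measures:
        jac[m] = jaccard_test(most_central_set(props1, m, jaccard_q),
                              most_central_set(props2, m, jaccard_q),
                              max(universe,
                                  len(most_central_set(props1, m, jaccard_q) |
                                      most_central_set(props2, m,
                                                       jaccard_q))))
    jac["hubs"] = jaccard_test(
        set(props1.hubs), set(props2.hubs),
        max(universe, len(set(props1.hubs) | set(props2.hubs))))

    rand = adjusted_rand_test(props1.clusters.labels, props2.clusters.labels,
                              n_perm=rand_n_perm,
                              seed=rng.integers(2 ** 31))

    return ComparisonResult(
        list(counts.taxon_ids), c1, c2, cdiff, c_p, c_adj,
        g1, g2, gdiff, g_p, jac, rand, n_perm, seed,
        group_names=design.group_names)
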