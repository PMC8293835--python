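"""From association matrix to network adjacency.

Sparsification selects the edges (hard threshold, Student t-test or
bootstrap on the correlations, or nothing for model-based measures that
already select edges).  Selected associations r* are transformed into
dissimilarities d and similarities s = 1 - d; alternatively
soft-thresholding raises correlations to a power beta > 1, yielding a
fully connected weighted network whose path metrics must use the
topological-overlap (TOM) dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (AdjacencyBundle, AssociationMatrix, CountMatrix,
                         SparsifiedAssociation)

__all__ = [
    "BootstrapSpec",
    "adjust_pvalues",
    "sparsify",
    "to_adjacency",
    "soft_threshold_adjacency",
    "tom_dissimilarity",
]

MODEL_BASED_MEASURES = ("nbhd_partial",)


@dataclass
class BootstrapSpec:
    reps: int = 999
    seed: Optional[int] = None
    alpha: float = 0.05
    adjust: str = "adaptiveBH"
    null: str = "shift"  # or "permutation"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("bootstrap needs reps >= 1")
        if self.null not in ("shift", "permutation"):
            raise ValueError("null must be 'shift' or 'permutation'")


def adjust_pvalues(p, method: str = "adaptiveBH") -> np.ndarray:
    """Multiple-testing adjustment of a p-value vector.

    ``adaptiveBH`` rescales Benjamini-Hochberg by Storey's estimate of
    the true-null proportion pi0 (lambda = 0.5), giving higher power
    when many hypotheses are non-null.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    mapping = {"bonferroni": "bonferroni", "holm": "holm",
               "BH": "fdr_bh", "BY": "fdr_by"}
    if method in mapping:
        return multipletests(p, method=mapping[method])[1]
    if method == "adaptiveBH":
        lam = 0.5
        pi0 = min(1.0, (np.sum(p > lam) / ((1.0 - lam) * p.size)))
        bh = multipletests(p, method="fdr_bh")[1]
        return np.clip(pi0 * bh, 0.0, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def _matrix_adjust(pmat: np.ndarray, method: str) -> np.ndarray:
    """Adjust the upper-triangle entries of a symmetric p-value matrix."""
    p = pmat.shape[0]
    iu = np.triu_indices(p, 1)
    adj = np.ones_like(pmat)
    adj[iu] = adjust_pvalues(pmat[iu], method)
    adj[(iu[1], iu[0])] = adj[iu]
    return adj


def _ttest_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for H0: r = 0 via t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    exact = np.abs(r) >= 1.0
    p[exact] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    finite = ~exact
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df=n - 2)
    return p


def sparsify(
    assoc: AssociationMatrix,
    method: str = "threshold",
    threshold: float = 0.3,
    alpha: float = 0.05,
    adjust: str = "adaptiveBH",
    counts: Optional[CountMatrix] = None,
    estimator: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    bootstrap: Optional[BootstrapSpec] = None,
    inclusive: bool = False,
) -> SparsifiedAssociation:
    """Select network edges from an association matrix.

    threshold: keep |r| strictly above the cut-off (``inclusive=True``
    switches to >=).  ttest: Student test of each correlation against
    zero, multiplicity-adjusted, keep adjusted p <= alpha.  bootstrap:
    resample the samples with replacement, re-estimate the association
    matrix each time, and count exceedances under a shifted null; the
    pseudo-count p-value (b+1)/(m+1) is never exactly zero.  Measures
    with built-in model selection (neighborhood selection) pass through
    unchanged.
    """
    r = np.array(assoc.values, dtype=float)
    np.fill_diagonal(r, 0.0)
    ids = list(assoc.taxon_ids)
    common = dict(taxon_ids=ids, measure=assoc.measure,
                  n_samples=assoc.n_samples)

    if assoc.measure in MODEL_BASED_MEASURES or method in ("none",
                                                           "model_based"):
        tag = "model_based" if assoc.measure in MODEL_BASED_MEASURES \
            else "none"
        return SparsifiedAssociation(r, method=tag, **common)

    if method == "threshold":
        if not (0 <= threshold < 1):
            raise ValueError("threshold must lie in [0, 1)")
        keep = np.abs(r) >= threshold if inclusive else np.abs(r) > threshold
        return SparsifiedAssociation(np.where(keep, r, 0.0),
                                     method="threshold", threshold=threshold,
                                     **common)

    if method == "ttest":
        n = assoc.n_samples
        if n < 3:
            raise ValueError("t-test sparsification needs the sample size "
                             "(n >= 3) recorded on the association matrix")
        pmat = _ttest_pvalues(r, n)
        np.fill_diagonal(pmat, 1.0)
        adj = _matrix_adjust(pmat, adjust)
        keep = adj <= alpha
        return SparsifiedAssociation(np.where(keep, r, 0.0), method="ttest",
                                     pvalues=pmat, adjusted_pvalues=adj,
                                     alpha=alpha, **common)

    if method == "bootstrap":
        if counts is None or estimator is None:
            raise ValueError("bootstrap sparsification requires the raw "
                             "counts and an estimator closure")
        spec = bootstrap or BootstrapSpec(alpha=alpha, adjust=adjust)
        rng = np.random.default_rng(spec.seed)
        X = counts.values
        n = X.shape[0]
        b = np.zeros_like(r)
        obs_abs = np.abs(r)
        for _ in range(spec.reps):
            if spec.null == "shift":
                idx = rng.integers(0, n, size=n)
                r_boot = np.asarray(estimator(X[idx]), dtype=float)
                exceed = np.abs(r_boot - r) >= obs_abs
            else:
                perm = np.column_stack([rng.permutation(X[:, j])
                                        for j in range(X.shape[1])])
                r_null = np.asarray(estimator(perm), dtype=float)
                np.fill_diagonal(r_null, 0.0)
                exceed = np.abs(r_null) >= obs_abs
            b += exceed
        pmat = (b + 1.0) / (spec.reps + 1.0)
        np.fill_diagonal(pmat, 1.0)
        adj = _matrix_adjust(pmat, spec.adjust)
        keep = adj <= spec.alpha
        return SparsifiedAssociation(np.where(keep, r, 0.0),
                                     method="bootstrap", pvalues=pmat,
                                     adjusted_pvalues=adj, alpha=spec.alpha,
                                     **common)

    raise ValueError(f"unknown sparsification method {method!r}")


def _distance(r: np.ndarray, mode: str) -> np.ndarray:
    if mode == "unsigned":
        return np.sqrt(np.clip(1.0 - r ** 2, 0.0, None))
    if mode == "signed":
        return np.sqrt(np.clip(0.5 * (1.0 - r), 0.0, None))
    if mode == "signedPos":
        return np.sqrt(np.clip(0.5 * (1.0 - np.clip(r, 0.0, None)),
                               0.0, None))
    raise ValueError(f"unknown dissimilarity mode {mode!r}; TOM is computed "
                     "via tom_dissimilarity")


def to_adjacency(sparse: SparsifiedAssociation, diss_mode: str = "signed",
                 weighted: bool = True,
                 include_negatives: bool = True) -> AdjacencyBundle:
    """Transform sparsified associations into the adjacency bundle.

    unsigned: d = sqrt(1 - r*^2) treats strong positive and negative
    association alike; signed: d = sqrt((1 - r*)/2) puts strongly
    negative pairs furthest apart; signedPos zeroes negative
    associations before the signed transform.  Unweighted networks
    replace similarities by the 0/1 edge indicator (optionally dropping
    negative-association edges) and use unit path lengths.
    """
    if diss_mode == "TOM":
        raise ValueError("build a metric bundle first, then call "
                         "tom_dissimilarity")
    r = np.array(sparse.values, dtype=float)
    if np.abs(r).max(initial=0.0) > 1.0:
        warnings.warn("associations outside [-1, 1] clipped before the "
                      "distance transform", RuntimeWarning)
        r = np.clip(r, -1.0, 1.0)
    selected = sparse.selected
    d_full = _distance(r, diss_mode)

    if weighted:
        # d is recorded for every selected pair; a pair at maximal
        # distance (s = 0, e.g. r* = -1 signed) carries no connection
        # strength and is not an edge
        diss = np.where(selected, d_full, 0.0)
        sim = np.where(selected, 1.0 - d_full, 0.0)
        edge = selected & (sim > 0)
        sim = np.where(edge, sim, 0.0)
    else:
        edge = selected.copy()
        if not include_negatives:
            edge &= r > 0
        sim = edge.astype(float)
        diss = edge.astype(float)
    return AdjacencyBundle(diss, sim, edge, list(sparse.taxon_ids),
                           diss_mode=diss_mode, weighted=weighted,
                           association=np.where(selected, r, 0.0))


def soft_threshold_adjacency(assoc: AssociationMatrix, beta: float,
                             sign_mode: str = "unsigned") -> AdjacencyBundle:
    """Soft-thresholding: similarities |r|^beta or ((1+r)/2)^beta.

    The network stays fully connected and weighted; shortest-path
    metrics use the TOM dissimilarity, which is precomputed into the
    bundle.
    """
    if beta <= 1:
        raise ValueError("soft-threshold power beta must be > 1")
    if sign_mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown sign mode {sign_mode!r}")
    r = np.array(assoc.values, dtype=float)
    if np.abs(r).max(initial=0.0) > 1.0:
        warnings.warn("associations outside [-1, 1] clipped before "
                      "soft-thresholding", RuntimeWarning)
        r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    if sign_mode == "unsigned":
        sim = np.abs(r) ** beta
    else:
        sim = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(sim, 0.0)
    edge = np.ones_like(sim, dtype=bool)
    np.fill_diagonal(edge, False)
    bundle = AdjacencyBundle(np.zeros_like(sim), sim, edge,
                             list(assoc.taxon_ids), diss_mode="TOM",
                             weighted=True, soft_power=beta, association=r)
    bundle.dissimilarity = tom_dissimilarity(bundle)
    return bundle


def tom_dissimilarity(bundle: AdjacencyBundle) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM of the similarity matrix.

    TOM_ij = (sum_u s_iu s_uj + s_ij) / (min(k_i, k_j) + 1 - s_ij)
    credits shared neighbors, so taxa in the same tightly knit module
    come out close even without a direct edge.
    """
    s = np.array(bundle.similarity, dtype=float)
    np.fill_diagonal(s, 0.0)
    k = s.sum(axis=1)
    shared = s @ s
    denom = np.minimum.outer(k, k) + 1.0 - s
    numer = shared + s
    bad = denom <= 0
    if bad[np.triu_indices_from(bad, 1)].any():
        warnings.warn("non-positive TOM denominator; dissimilarity set to 1",
                      RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(bad, 0.0, numer / np.where(bad, 1.0, denom))
    diss = 1.0 - tom
    diss = np.clip(0.5 * (diss + diss.T), 0.0, 1.0)
    np.fill_diagonal(diss, 0.0)
    return diss
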