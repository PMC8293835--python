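"""Sample dissimilarity networks: nodes are subjects, not taxa.

A dissimilarity between the microbial compositions of each pair of
samples is computed (Euclidean, Bray-Curtis, symmetrized
Kullback-Leibler, Jensen-Shannon, compositional KLD or the Aitchison
distance), scaled to [0, 1], and sparsified with the k-nearest-neighbor
rule; the resulting adjacency bundle feeds the same analysis and
comparison stack as the taxon networks.  Only the Aitchison distance
and the compositional KLD are invariant to the compositional
constraint; the others warn on raw compositions.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import (AdjacencyBundle, CountMatrix, NormalizedMatrix,
                         SampleDissimilarity)
from .preprocess import clr_transform

__all__ = ["sample_dissimilarity", "scale_dissimilarity", "knn_sparsify"]

_DIVERGENCES = ("kld", "jeffrey", "jensen_shannon", "comp_kld")
_AWARE = ("aitchison", "comp_kld")


def _jeffrey(X: np.ndarray) -> np.ndarray:
    """Jeffrey's divergence: KLD(k||l) + KLD(l||k), symmetric."""
    L = np.log(X)
    n = X.shape[0]
    d = np.zeros((n, n))
    for k in range(n):
        diff = L[k] - L  # log(x_k / x_l), rows l
        d[k] = ((X[k] - X) * diff).sum(axis=1)
    return d


def _jensen_shannon(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    d = np.zeros((n, n))
    for k in range(n):
        m = 0.5 * (X[k] + X)
        kl1 = (X[k] * np.log(X[k] / m)).sum(axis=1)
        kl2 = (X * np.log(X / m)).sum(axis=1)
        d[k] = 0.5 * kl1 + 0.5 * kl2
    return d


def _comp_kld(X: np.ndarray) -> np.ndarray:
    """Scale-invariant symmetric divergence on component ratios:
    (p/2) * log( mean(x/y) * mean(y/x) ); zero iff x is proportional
    to y."""
    n, p = X.shape
    d = np.zeros((n, n))
    for k in range(n):
        ratio = X[k] / X
        m1 = ratio.mean(axis=1)
        m2 = (1.0 / ratio).mean(axis=1)
        d[k] = 0.5 * p * np.log(m1 * m2)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def sample_dissimilarity(
        norm: Union[NormalizedMatrix, CountMatrix],
        method: str = "aitchison") -> SampleDissimilarity:
    """Pairwise dissimilarity between sample compositions.

    bray_curtis = sum|x_k - x_l| / sum(x_k + x_l); kld (and jeffrey)
    is the symmetrized Kullback-Leibler divergence; jensen_shannon
    uses the mixture form; aitchison is the Euclidean distance between
    clr-transformed rows; comp_kld is a scale-invariant symmetrized
    divergence of the component ratios.  Divergence methods require
    strictly positive simplex rows (run replace_zeros first).
    """
    X = np.asarray(norm.values, dtype=float)
    ids = list(norm.sample_ids)
    if np.any(X < 0):
        raise ValueError("negative entries in input")
    if method in _DIVERGENCES or method == "aitchison":
        if np.any(X == 0):
            raise ValueError(f"{method} requires strictly positive rows; "
                             "apply replace_zeros first")
    on_simplex = np.allclose(X.sum(axis=1), 1.0, atol=1e-6)
    if method not in _AWARE and on_simplex:
        warnings.warn(f"{method} is not compositionally aware; applied to "
                      "raw compositions it may induce compositional "
                      "effects", RuntimeWarning)

    if method == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif method == "bray_curtis":
        d = squareform(pdist(X, metric="braycurtis"))
    elif method in ("kld", "jeffrey"):
        d = _jeffrey(X)
    elif method == "jensen_shannon":
        d = _jensen_shannon(X)
    elif method == "comp_kld":
        d = _comp_kld(X)
    elif method == "aitchison":
        d = squareform(pdist(clr_transform(X), metric="euclidean"))
    else:
        raise ValueError(f"unknown dissimilarity method {method!r}")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return SampleDissimilarity(np.clip(d, 0.0, None), ids, method)


def scale_dissimilarity(d: SampleDissimilarity) -> SampleDissimilarity:
    """Scale to [0, 1] by dividing by the maximum off-diagonal entry."""
    vals = np.array(d.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite dissimilarities")
    mx = vals.max()
    if mx == 0:
        warnings.warn("all-zero dissimilarity matrix left unchanged",
                      RuntimeWarning)
        return SampleDissimilarity(vals, list(d.sample_ids), d.method,
                                   scaled=True)
    return SampleDissimilarity(vals / mx, list(d.sample_ids), d.method,
                               scaled=True)


def knn_sparsify(d: SampleDissimilarity, k: int = 3) -> AdjacencyBundle:
    """k-nearest-neighbor sparsification (union rule).

    An edge (k, l) is kept iff l is among the k nearest neighbors of k
    or vice versa, so every node keeps degree >= k.  Ties at the k-th
    neighbor include all tied samples.  Requires a scaled matrix so
    that similarity s = 1 - d is well defined.
    """
    vals = np.array(d.values, dtype=float)
    n = vals.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must lie in [1, n-1]; got {k} for n={n}")
    if not d.scaled and vals.max(initial=0.0) > 1.0:
        warnings.warn("dissimilarities exceed 1; scaling to [0, 1] before "
                      "similarity transform", RuntimeWarning)
        vals = vals / vals.max()
    neighbor = np.zeros((n, n), dtype=bool)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        dist = vals[i, others]
        kth = np.partition(dist, k - 1)[k - 1]
        sel = others[dist <= kth + 1e-12]  # ties included
        neighbor[i, sel] = True
    edge = neighbor | neighbor.T
    sim = np.where(edge, 1.0 - vals, 0.0)
    diss = np.where(edge, vals, 0.0)
    # an edge at maximum dissimilarity has zero similarity; keep it as an
    # edge for path metrics but it carries no connection strength
    return AdjacencyBundle(diss, sim, edge, list(d.sample_ids),
                           diss_mode="sample", weighted=True,
                           association=None)
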