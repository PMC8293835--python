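"""Differential association analysis between two groups.

Tests each taxon pair for a change in association strength: Fisher's
z-test for correlation-type measures, and a label-permutation test for
any association measure (the non-parametric route for proportionality
and partial correlations).  Significant pairs form the differential
network, whose edge weights are |r1 - r2|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .containers import AssociationMatrix, CountMatrix, GroupDesign
from .netbuild import adjust_pvalues

__all__ = [
    "DiffAssocResult",
    "DiffNetwork",
    "fisher_z_test",
    "permutation_diff_test",
    "differential_network",
]

FISHER_MEASURES = ("pearson", "spearman", "bicor", "sparcc")


@dataclass
class DiffAssocResult:
    assoc1: AssociationMatrix
    assoc2: AssociationMatrix
    pvalues: np.ndarray
    adjusted: np.ndarray
    method: str
    statistic: Optional[np.ndarray] = None

    @property
    def taxon_ids(self) -> list[str]:
        return self.assoc1.taxon_ids


@dataclass
class DiffNetwork:
    weights: np.ndarray
    taxon_ids: list[str]
    alpha: float

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def _matrix_adjust(pmat: np.ndarray, method: str) -> np.ndarray:
    p = pmat.shape[0]
    iu = np.triu_indices(p, 1)
    adj = np.ones_like(pmat)
    adj[iu] = adjust_pvalues(pmat[iu], method)
    adj[(iu[1], iu[0])] = adj[iu]
    return adj


def fisher_z_test(assoc1: AssociationMatrix, assoc2: AssociationMatrix,
                  n1: Optional[int] = None, n2: Optional[int] = None,
                  adjust: str = "adaptiveBH") -> DiffAssocResult:
    """Fisher z-test for equality of two correlation matrices.

    z_g = atanh(r_g); the statistic (z1 - z2) / sqrt(1/(n1-3) +
    1/(n2-3)) is referred to the standard normal, two-sided.  Only
    correlation-type measures are admissible; |r| = 1 is clipped to
    1 - 1e-7 with a warning.
    """
    if assoc1.measure not in FISHER_MEASURES or \
            assoc2.measure not in FISHER_MEASURES:
        raise ValueError(
            f"Fisher's z-test applies to correlation measures "
            f"{FISHER_MEASURES}; got {assoc1.measure!r}/{assoc2.measure!r} "
            "(use permutation_diff_test instead)")
    if assoc1.taxon_ids != assoc2.taxon_ids:
        raise ValueError("association matrices must share taxon ids")
    n1 = n1 if n1 is not None else assoc1.n_samples
    n2 = n2 if n2 is not None else assoc2.n_samples
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher's z-test needs more than 3 samples per "
                         "group")
    r1 = np.array(assoc1.values, dtype=float)
    r2 = np.array(assoc2.values, dtype=float)
    for r in (r1, r2):
        over = np.abs(r) >= 1.0
        np.fill_diagonal(over, False)
        if over.any():
            warnings.warn("|r| = 1 clipped to 1 - 1e-7 for the z "
                          "transform", RuntimeWarning)
        np.clip(r, -(1 - 1e-7), 1 - 1e-7, out=r)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    pmat = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(pmat, 1.0)
    pmat = 0.5 * (pmat + pmat.T)
    adj = _matrix_adjust(pmat, adjust)
    return DiffAssocResult(assoc1, assoc2, pmat, adj, "fisher_z",
                           statistic=z)


def permutation_diff_test(
    counts: CountMatrix,
    design: GroupDesign,
    estimator: Callable[[CountMatrix], AssociationMatrix],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    adjust: str = "adaptiveBH",
    max_retries: int = 10,
) -> DiffAssocResult:
    """Label-permutation test of per-pair association differences.

    ``estimator`` maps a CountMatrix subset to an AssociationMatrix
    (any measure).  The observed |r1 - r2| per pair is referred to the
    permutation distribution of the same quantity under shuffled group
    labels; p = (b+1)/(n_perm+1), then multiplicity-adjusted.
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives coarse p-values", RuntimeWarning)

    def estimate(idx: np.ndarray) -> np.ndarray:
        sub = CountMatrix(counts.values[idx],
                          [counts.sample_ids[i] for i in idx],
                          list(counts.taxon_ids))
        return np.asarray(estimator(sub).values, dtype=float)

    idx1 = np.nonzero(design.mask1)[0]
    idx2 = np.nonzero(design.mask2)[0]
    a1 = estimator(CountMatrix(counts.values[idx1],
                               [counts.sample_ids[i] for i in idx1],
                               list(counts.taxon_ids)))
    a2 = estimator(CountMatrix(counts.values[idx2],
                               [counts.sample_ids[i] for i in idx2],
                               list(counts.taxon_ids)))
    obs = np.abs(np.asarray(a1.values) - np.asarray(a2.values))

    n = counts.n_samples
    n1 = idx1.size
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = np.abs(estimate(perm[:n1]) - estimate(perm[n1:]))
                break
            except Exception:
                if attempt == max_retries:
                    raise
        exceed += d >= obs - 1e-12
    pmat = (exceed + 1.0) / (n_perm + 1.0)
    np.fill_diagonal(pmat, 1.0)
    adj = _matrix_adjust(pmat, adjust)
    return DiffAssocResult(a1, a2, pmat, adj, "permutation")


def differential_network(result: DiffAssocResult,
                         alpha: float = 0.05) -> DiffNetwork:
    """Connect taxon pairs whose association differs at level alpha.

    Edge weight is the absolute association difference |r1 - r2|.
    """
    if result.adjusted is None:
        raise ValueError("adjusted p-values required")
    diff = np.abs(np.asarray(result.assoc1.values) -
                  np.asarray(result.assoc2.values))
    keep = result.adjusted <= alpha
    np.fill_diagonal(keep, False)
    return DiffNetwork(np.where(keep, diff, 0.0),
                       list(result.taxon_ids), alpha)
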