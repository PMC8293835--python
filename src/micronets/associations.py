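"""Taxon-taxon association estimation.

Traditional correlation measures (Pearson, Spearman, biweight
midcorrelation) are offered for transformed data, alongside the
compositionally aware estimators: SparCC basis correlations,
proportionality rho on clr-transformed data, and conditional
dependence via lasso neighborhood selection with stability-based model
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .containers import AssociationMatrix, CountMatrix, NormalizedMatrix
from .estimators import NeighborhoodSelection, SparCC
from .preprocess import clr_transform

__all__ = [
    "SparccConfig",
    "NbhdConfig",
    "correlate",
    "sparcc",
    "proportionality_rho",
    "neighborhood_select",
]


@dataclass
class SparccConfig:
    n_outer: int = 20
    n_inner: int = 10
    exclusion_threshold: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if not (0 < self.exclusion_threshold < 1):
            raise ValueError("exclusion_threshold must be in (0, 1)")


@dataclass
class NbhdConfig:
    lambda_grid: Optional[list[float]] = None
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_subsample_ratio: Optional[float] = None
    stars_reps: int = 20
    instability_threshold: float = 0.05
    symmetrize_rule: str = "or"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.instability_threshold < 0.5):
            raise ValueError("instability_threshold must be in (0, 0.5)")
        if self.symmetrize_rule not in ("and", "or"):
            raise ValueError("symmetrize_rule must be 'and' or 'or'")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.size == 0:
                raise ValueError("empty lambda grid")
            if np.any(np.diff(g) > 0):
                raise ValueError("lambda_grid must be sorted descending")


def _bicor_standardize(x: np.ndarray, c: float = 9.0) -> Optional[np.ndarray]:
    """Tukey-biweight standardized column, or None if MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (c * mad)
    w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    centered = (x - med) * w
    norm = np.sqrt(np.sum(centered ** 2))
    if norm == 0:
        return None
    return centered / norm


def correlate(norm: Union[NormalizedMatrix, CountMatrix],
              method: str = "pearson") -> AssociationMatrix:
    """Pairwise Pearson, Spearman or biweight midcorrelation (bicor).

    Spearman is Pearson on average ranks; bicor weights observations
    around the column median with Tukey biweights (tuning constant 9)
    and falls back to Pearson for columns with zero median absolute
    deviation.  Constant columns yield zero association with a warning.
    """
    if method not in ("pearson", "spearman", "bicor"):
        raise ValueError(f"unknown correlation method {method!r}")
    X = np.asarray(norm.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    n, p = X.shape
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    taxon_ids = list(norm.taxon_ids)

    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)

    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s); their "
                      "associations are set to 0", RuntimeWarning)

    if method == "bicor":
        std_cols = [None if const[j] else _bicor_standardize(X[:, j])
                    for j in range(p)]
        fallback = [j for j in range(p)
                    if not const[j] and std_cols[j] is None]
        if fallback:
            warnings.warn("zero MAD in columns "
                          f"{[taxon_ids[j] for j in fallback]}; falling back "
                          "to Pearson for these", RuntimeWarning)
        pear = _safe_corrcoef(X, const)
        r = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                if const[i] or const[j]:
                    val = 0.0
                elif std_cols[i] is None or std_cols[j] is None:
                    val = pear[i, j]
                else:
                    val = float(std_cols[i] @ std_cols[j])
                r[i, j] = r[j, i] = np.clip(val, -1.0, 1.0)
    else:
        r = _safe_corrcoef(X, const)

    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, taxon_ids, measure=method, n_samples=n)


def _safe_corrcoef(X: np.ndarray, const: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def sparcc(counts: CountMatrix,
           cfg: Optional[SparccConfig] = None) -> AssociationMatrix:
    """SparCC correlations from log-ratio variances (see estimators.SparCC)."""
    cfg = cfg or SparccConfig()
    est = SparCC(n_outer=cfg.n_outer, n_inner=cfg.n_inner,
                 exclusion_threshold=cfg.exclusion_threshold,
                 random_state=cfg.seed).fit(counts.values)
    return AssociationMatrix(est.correlation_, list(counts.taxon_ids),
                             measure="sparcc", n_samples=counts.n_samples)


def proportionality_rho(
        data: Union[CountMatrix, NormalizedMatrix]) -> AssociationMatrix:
    """Proportionality rho on clr-transformed data.

    rho_ij = 1 - var(g_i - g_j) / (var(g_i) + var(g_j)) with g the clr
    columns; equals 1 iff two components' logs differ by a constant.
    """
    X = np.asarray(data.values, dtype=float)
    if np.any(X <= 0):
        raise ValueError("proportionality requires strictly positive input; "
                         "apply replace_zeros first")
    G = clr_transform(X)
    v = G.var(axis=0, ddof=1)
    c = np.cov(G, rowvar=False, ddof=1)
    denom = v[:, None] + v[None, :]
    zero_var = v == 0
    if zero_var.any():
        warnings.warn("zero-variance clr column(s); rho set to 0 there",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * c / denom
    rho[np.isnan(rho)] = 0.0
    rho[zero_var, :] = 0.0
    rho[:, zero_var] = 0.0
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return AssociationMatrix(rho, list(data.taxon_ids), measure="rho",
                             n_samples=X.shape[0])


def neighborhood_select(clr_matrix: NormalizedMatrix,
                        cfg: Optional[NbhdConfig] = None) -> AssociationMatrix:
    """Conditional dependence network from clr data (StARS-selected lasso)."""
    if clr_matrix.scale != "clr-log":
        raise ValueError("neighborhood selection expects clr-transformed "
                         "input (scale='clr-log')")
    cfg = cfg or NbhdConfig()
    est = NeighborhoodSelection(
        lambda_grid=cfg.lambda_grid, n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        subsample_ratio=cfg.stars_subsample_ratio, n_reps=cfg.stars_reps,
        instability_threshold=cfg.instability_threshold,
        symmetrize_rule=cfg.symmetrize_rule,
        random_state=cfg.seed).fit(clr_matrix.values)
    return AssociationMatrix(est.partial_correlation_,
                             list(clr_matrix.taxon_ids),
                             measure="nbhd_partial",
                             n_samples=clr_matrix.n_samples)
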