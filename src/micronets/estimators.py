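"""Scikit-learn style estimators for compositionally aware association inference.

Two estimation problems warrant a fitted-model interface: SparCC basis
correlations and sparse conditional-dependence (partial correlation)
selection.  Both follow the sklearn contract (``fit``, ``get_params``,
fitted attributes with trailing underscores) so they compose with
sklearn model-selection tooling; the functional wrappers in
:mod:`micronets.associations` delegate here.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_array

from .preprocess import clr_transform

__all__ = ["ClrTransformer", "SparCC", "NeighborhoodSelection"]


class ClrTransformer(TransformerMixin, BaseEstimator):
    """Centered log-ratio transform as a stateless sklearn transformer.

    ``pseudocount`` (default 0) is added before taking logs; leave at 0
    when zeros have already been replaced.
    """

    def __init__(self, pseudocount: float = 0.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X) + self.pseudocount
        return clr_transform(X)


def _logratio_variances(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) for all pairs, from log fractions."""
    v = log_fracs.var(axis=0, ddof=1)
    c = np.cov(log_fracs, rowvar=False, ddof=1)
    return v[:, None] + v[None, :] - 2.0 * c


def _solve_basis(t: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Solve the basis-variance linear system restricted to included pairs.

    Under the sparsity approximation (taxa uncorrelated on average) the
    row sums of the log-ratio variance matrix satisfy a linear system
    in the latent basis variances w: with no exclusions the system
    matrix is (p-2) I + 1 1^T.
    """
    d = included.sum(axis=1).astype(float)
    if np.any(d < 1):
        raise np.linalg.LinAlgError(
            "basis-variance system under-determined: a component lost all "
            "its pairs; use fewer exclusion iterations or a higher "
            "exclusion threshold")
    A = included.astype(float)
    A[np.diag_indices_from(A)] = d
    t_rows = (t * included).sum(axis=1)
    return np.linalg.solve(A, t_rows)


def _basis_correlations(t: np.ndarray, n_inner: int,
                        exclusion_threshold: float) -> np.ndarray:
    p = t.shape[0]
    included = ~np.eye(p, dtype=bool)
    for _ in range(n_inner + 1):
        w = _solve_basis(t, included)
        bad = w <= 0
        if np.any(bad):
            warnings.warn(
                "negative basis variance estimated for "
                f"{int(bad.sum())} component(s); their correlations are "
                "set to 0", RuntimeWarning)
            w = np.where(bad, np.nan, w)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        with np.errstate(invalid="ignore"):
            rho = (w[:, None] + w[None, :] - t) / denom
        rho[np.isnan(rho)] = 0.0
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest still-included pair, if above threshold
        masked = np.where(included, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
    return 0.5 * (rho + rho.T)


class SparCC(BaseEstimator):
    """SparCC basis correlations for compositional count data.

    Correlations between latent absolute abundances are approximated
    from log-ratio variances under the assumption that taxa are
    sparsely correlated.  Zeros are handled by Bayesian resampling: in
    each outer repetition the sample compositions are drawn from a
    Dirichlet posterior (uniform prior, counts + 1) and the basis
    system is re-solved; an inner loop iteratively excludes the most
    strongly correlated pair to reinforce the sparsity assumption.
    The final estimate is the element-wise median across repetitions.

    Parameters
    ----------
    n_outer : resampling repetitions (>= 1).
    n_inner : maximum strong-pair exclusion iterations per repetition.
    exclusion_threshold : |rho| above which the strongest pair is
        excluded from the basis system.
    random_state : seed for the Dirichlet resampling.

    Attributes
    ----------
    correlation_ : (p, p) symmetric estimate, unit diagonal.  Entries
        may fall outside [-1, 1]; ``correlation_clipped_`` is the
        version clipped for downstream distance transforms.
    """

    def __init__(self, n_outer: int = 20, n_inner: int = 10,
                 exclusion_threshold: float = 0.1, random_state=None):
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.exclusion_threshold = exclusion_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        n, p = X.shape
        if p < 4:
            raise ValueError("SparCC needs at least 4 taxa (the basis "
                             "variance system requires p > 3)")
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if not (0 < self.exclusion_threshold < 1):
            raise ValueError("exclusion_threshold must be in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        reps = np.empty((self.n_outer, p, p))
        posterior = X + 1.0  # Dirichlet posterior with uniform prior
        for r in range(self.n_outer):
            gam = rng.standard_gamma(posterior)
            fracs = gam / gam.sum(axis=1, keepdims=True)
            t = _logratio_variances(np.log(fracs))
            reps[r] = _basis_correlations(t, self.n_inner,
                                          self.exclusion_threshold)
        rho = np.median(reps, axis=0)
        rho = 0.5 * (rho + rho.T)
        np.fill_diagonal(rho, 1.0)
        self.correlation_ = rho
        self.correlation_clipped_ = np.clip(rho, -1.0, 1.0)
        self.n_features_in_ = p
        self.n_samples_ = n
        return self


class NeighborhoodSelection(BaseEstimator):
    """Sparse conditional-dependence network via neighborhood selection.

    Each clr-transformed taxon is lasso-regressed on all others over a
    decreasing penalty grid; the penalty is chosen by StARS stability
    selection (repeated subsampling, picking the densest graph whose
    monotonized edge instability stays below the threshold).  The two
    directed regressions per pair are combined by an AND or OR rule and
    reported as a signed partial-correlation proxy, the sign-consistent
    geometric mean sqrt(beta_ij * beta_ji).

    Attributes
    ----------
    partial_correlation_ : (p, p) symmetric proxy matrix, unit diagonal.
    adjacency_ : boolean edge indicator.
    lambda_ : selected penalty.
    instability_path_ : monotonized instability per grid point.
    """

    def __init__(self, lambda_grid=None, n_lambda: int = 20,
                 lambda_min_ratio: float = 0.01,
                 subsample_ratio=None, n_reps: int = 20,
                 instability_threshold: float = 0.05,
                 symmetrize_rule: str = "or", random_state=None):
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.subsample_ratio = subsample_ratio
        self.n_reps = n_reps
        self.instability_threshold = instability_threshold
        self.symmetrize_rule = symmetrize_rule
        self.random_state = random_state

    def _grid(self, Z: np.ndarray) -> np.ndarray:
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0:
                raise ValueError("empty lambda grid")
            if np.any(np.diff(grid) > 0):
                raise ValueError("lambda grid must be sorted descending")
            return grid
        n = Z.shape[0]
        lam_max = 0.0
        for j in range(Z.shape[1]):
            others = np.delete(Z, j, axis=1)
            lam_max = max(lam_max,
                          np.abs(others.T @ Z[:, j]).max() / n)
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambda)

    @staticmethod
    def _directed_selection(Z: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """(p, p, L) boolean tensor: taxon j selected for node i at grid l."""
        n, p = Z.shape
        sel = np.zeros((p, p, grid.size), dtype=bool)
        for i in range(p):
            others = np.delete(np.arange(p), i)
            _, coefs, _ = lasso_path(Z[:, others], Z[:, i], alphas=grid)
            sel[i, others, :] = np.abs(coefs) > 1e-10
        return sel

    def _combine(self, sel: np.ndarray) -> np.ndarray:
        if self.symmetrize_rule == "and":
            return sel & sel.swapaxes(0, 1)
        if self.symmetrize_rule == "or":
            return sel | sel.swapaxes(0, 1)
        raise ValueError(f"unknown symmetrize rule {self.symmetrize_rule!r}")

    def fit(self, X, y=None):
        Z = check_array(X)
        n, p = Z.shape
        if n <= 10:
            raise ValueError("neighborhood selection needs n > 10")
        if not (0 < self.instability_threshold < 0.5):
            raise ValueError("instability_threshold must be in (0, 0.5)")
        Z = Z - Z.mean(axis=0)
        grid = self._grid(Z)
        ratio = self.subsample_ratio
        if ratio is None:
            ratio = 0.8 if n <= 144 else 10.0 * np.sqrt(n) / n
        b = max(2, int(np.floor(ratio * n)))
        rng = np.random.default_rng(self.random_state)

        freq = np.zeros((p, p, grid.size))
        for _ in range(self.n_reps):
            idx = rng.choice(n, size=b, replace=False)
            sub = Z[idx] - Z[idx].mean(axis=0)
            freq += self._combine(self._directed_selection(sub, grid))
        theta = freq / self.n_reps
        iu = np.triu_indices(p, 1)
        instab = (2.0 * theta * (1.0 - theta))[iu[0], iu[1], :].mean(axis=0)
        # monotonize from the sparse end and take the densest acceptable graph
        instab_mono = np.maximum.accumulate(instab)
        ok = np.nonzero(instab_mono <= self.instability_threshold)[0]
        pick = ok[-1] if ok.size else 0
        self.lambda_ = float(grid[pick])
        self.instability_path_ = instab_mono
        self.lambda_grid_ = grid

        # refit on the full data at the selected penalty
        beta = np.zeros((p, p))
        for i in range(p):
            others = np.delete(np.arange(p), i)
            _, coefs, _ = lasso_path(Z[:, others], Z[:, i],
                                     alphas=[self.lambda_])
            beta[i, others] = coefs[:, 0]

        directed = np.abs(beta) > 1e-10
        if self.symmetrize_rule == "and":
            adj = directed & directed.T
        else:
            adj = directed | directed.T
        if not adj.any():
            warnings.warn("no edges selected at any penalty; returning an "
                          "empty network", RuntimeWarning)

        value = np.zeros((p, p))
        both = directed & directed.T
        sign_agree = both & (np.sign(beta) == np.sign(beta.T))
        value[sign_agree] = (np.sign(beta) *
                             np.sqrt(np.abs(beta * beta.T)))[sign_agree]
        if self.symmetrize_rule == "or":
            only_one = adj & ~both
            single = np.where(directed, beta, beta.T)
            value[only_one] = single[only_one]
        value = np.where(adj, value, 0.0)
        value = 0.5 * (value + value.T)
        over = np.abs(value) > 1.0
        if over.any():
            warnings.warn("partial-correlation proxy outside [-1, 1]; "
                          "clipping", RuntimeWarning)
            value = np.clip(value, -1.0, 1.0)
        np.fill_diagonal(value, 1.0)
        self.partial_correlation_ = value
        self.adjacency_ = adj
        self.n_features_in_ = p
        self.n_samples_ = n
        return self
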