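"""Synthetic compositional count data with known association structure.

The generative bridge is logistic-normal-multinomial: a sparse
precision matrix over latent log-abundances defines the ground-truth
conditional-dependence graph; latent vectors are drawn multivariate
normal, mapped to compositions by softmax, and counts are multinomial
at sample-specific sequencing depths.  The recorded truth therefore
refers to latent-scale associations; the compositional constraint and
the multinomial sampling then distort naive estimates exactly the way
they do in real sequencing data (excess zeros, varying depth,
compositional bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .containers import CountMatrix

__all__ = ["SyntheticDataset", "generate_synthetic", "generate_two_groups",
           "write_dataset", "read_dataset"]


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    truth_correlation: np.ndarray
    truth_precision: np.ndarray
    truth_precision_support: np.ndarray
    latent: Optional[np.ndarray]
    mu: np.ndarray
    depth_range: tuple[int, int]
    graph_model: str
    seed: Optional[int]

    @property
    def n_samples(self) -> int:
        return self.counts.n_samples

    @property
    def n_taxa(self) -> int:
        return self.counts.n_taxa


def _support(p: int, graph_model: str, rng: np.random.Generator,
             edge_prob: Optional[float], block_size: int) -> np.ndarray:
    A = np.zeros((p, p), dtype=bool)
    if graph_model == "chain":
        for i in range(p - 1):
            A[i, i + 1] = A[i + 1, i] = True
    elif graph_model == "cluster":
        for start in range(0, p, block_size):
            idx = np.arange(start, min(start + block_size, p))
            for a in idx:
                for b in idx:
                    if a < b:
                        A[a, b] = A[b, a] = True
    elif graph_model == "erdos_renyi":
        prob = edge_prob if edge_prob is not None else 2.0 / (p - 1)
        upper = rng.random((p, p)) < prob
        upper = np.triu(upper, 1)
        A = upper | upper.T
    else:
        raise ValueError(f"unknown graph model {graph_model!r}")
    return A


def _build_precision(support: np.ndarray, strength: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Symmetric positive-definite precision with the given support."""
    p = support.shape[0]
    B = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    edges = support[iu]
    vals = strength * rng.choice([-1.0, 1.0], size=int(edges.sum()))
    B[iu[0][edges], iu[1][edges]] = vals
    B = B + B.T
    return _make_pd(B)


def _make_pd(B: np.ndarray, max_jitter: int = 10) -> np.ndarray:
    p = B.shape[0]
    lam_min = np.linalg.eigvalsh(B)[0]
    shift = max(0.0, -lam_min) + 0.1
    omega = B + shift * np.eye(p)
    for _ in range(max_jitter):
        if np.linalg.eigvalsh(omega)[0] > 1e-10:
            return omega
        omega = omega + 0.1 * np.eye(p)
    raise ValueError("could not construct a positive-definite precision "
                     "matrix")


def _cov2cor(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def _bound_condition(R: np.ndarray, target: float) -> np.ndarray:
    lam = np.linalg.eigvalsh(R)
    cond = lam[-1] / max(lam[0], 1e-12)
    if cond <= target:
        return R
    c = (lam[-1] - target * lam[0]) / (target - 1.0)
    return (R + c * np.eye(R.shape[0])) / (1.0 + c)


def generate_synthetic(
    p: int = 50,
    n: int = 100,
    graph_model: str = "erdos_renyi",
    target_condition: float = 100.0,
    depth_range: tuple[int, int] = (1000, 50000),
    seed: Optional[int] = None,
    edge_prob: Optional[float] = None,
    block_size: int = 5,
    partial_strength: float = 0.3,
    mu_sd: float = 3.5,
    keep_latent: bool = True,
) -> SyntheticDataset:
    """Draw a synthetic compositional count dataset with known truth.

    A sparse precision matrix over the chosen graph support (chain,
    cluster blocks, or Erdos-Renyi) is made positive definite, inverted
    and rescaled to a unit-diagonal latent correlation with condition
    number at most ``target_condition``.  Latent log-abundances are
    multivariate normal around taxon-specific means (spread ``mu_sd``,
    producing realistic abundance heterogeneity and hence zero
    fractions); compositions arise by softmax and counts by multinomial
    sampling at depths uniform over ``depth_range``.
    """
    if p < 4:
        raise ValueError("p must be >= 4")
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    support = _support(p, graph_model, rng, edge_prob, block_size)
    omega = _build_precision(support, partial_strength, rng)
    cov = np.linalg.inv(omega)
    R = _bound_condition(_cov2cor(cov), target_condition)

    mu = rng.normal(0.0, mu_sd, size=p)
    L = np.linalg.cholesky(R)
    latent = mu + rng.standard_normal((n, p)) @ L.T
    expz = np.exp(latent - latent.max(axis=1, keepdims=True))
    comps = expz / expz.sum(axis=1, keepdims=True)
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n)
    counts = np.vstack([rng.multinomial(depths[k], comps[k])
                        for k in range(n)]).astype(float)
    cm = CountMatrix(counts, [f"S{k}" for k in range(n)],
                     [f"T{i}" for i in range(p)])
    return SyntheticDataset(cm, R, omega, support,
                            latent if keep_latent else None, mu,
                            tuple(depth_range), graph_model, seed)


def _regenerate(ds: SyntheticDataset, omega: np.ndarray,
                rng: np.random.Generator) -> SyntheticDataset:
    n, p = ds.n_samples, ds.n_taxa
    cov = np.linalg.inv(omega)
    R = _cov2cor(cov)
    L = np.linalg.cholesky(R)
    latent = ds.mu + rng.standard_normal((n, p)) @ L.T
    expz = np.exp(latent - latent.max(axis=1, keepdims=True))
    comps = expz / expz.sum(axis=1, keepdims=True)
    depths = rng.integers(ds.depth_range[0], ds.depth_range[1] + 1, size=n)
    counts = np.vstack([rng.multinomial(depths[k], comps[k])
                        for k in range(n)]).astype(float)
    support = np.abs(omega) > 1e-10
    np.fill_diagonal(support, False)
    cm = CountMatrix(counts, list(ds.counts.sample_ids),
                     list(ds.counts.taxon_ids))
    return SyntheticDataset(cm, R, omega, support, latent, ds.mu,
                            ds.depth_range, ds.graph_model, None)


def generate_two_groups(
    base: SyntheticDataset,
    perturbation: str = "none",
    magnitude: float = 0,
    seed: Optional[int] = None,
) -> tuple[SyntheticDataset, SyntheticDataset, list[tuple[str, str]]]:
    """Two group datasets: group 1 from the base model, group 2 perturbed.

    ``none`` draws two independent datasets from the identical model
    (the null).  ``rewire_edges`` changes exactly ``magnitude`` pairs
    of the precision support, alternating between deleting an existing
    edge and adding a new one.  ``scale_correlations`` multiplies all
    edge strengths by ``magnitude``.  The changed pairs are returned as
    ground truth for differential-association power checks.
    """
    rng = np.random.default_rng(seed)
    omega1 = np.array(base.truth_precision)
    ids = base.counts.taxon_ids
    changed: list[tuple[str, str]] = []

    if perturbation == "none":
        omega2 = omega1.copy()
    elif perturbation == "rewire_edges":
        m = int(magnitude)
        omega2 = omega1.copy()
        support = np.abs(omega2) > 1e-10
        np.fill_diagonal(support, False)
        iu = np.triu_indices(omega2.shape[0], 1)
        present = [(i, j) for i, j in zip(*iu) if support[i, j]]
        absent = [(i, j) for i, j in zip(*iu) if not support[i, j]]
        rng.shuffle(present)
        rng.shuffle(absent)
        strength = np.abs(omega1[np.abs(omega1 -
                                        np.diag(np.diag(omega1))) > 1e-10])
        val = float(np.median(strength)) if strength.size else 0.3
        for t in range(m):
            if t % 2 == 0 and present:
                i, j = present.pop()
                omega2[i, j] = omega2[j, i] = 0.0
            elif absent:
                i, j = absent.pop()
                sgn = rng.choice([-1.0, 1.0])
                omega2[i, j] = omega2[j, i] = sgn * val
            elif present:
                i, j = present.pop()
                omega2[i, j] = omega2[j, i] = 0.0
            else:
                raise ValueError("no pairs left to rewire")
            changed.append((ids[i], ids[j]))
    elif perturbation == "scale_correlations":
        omega2 = omega1.copy()
        off = ~np.eye(omega2.shape[0], dtype=bool)
        edges = off & (np.abs(omega2) > 1e-10)
        omega2[edges] *= magnitude
        iu = np.triu_indices(omega2.shape[0], 1)
        changed = [(ids[i], ids[j]) for i, j in zip(*iu) if edges[i, j]]
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")

    if np.linalg.eigvalsh(omega2)[0] <= 1e-10:
        for _ in range(10):
            omega2 = omega2 + 0.1 * np.eye(omega2.shape[0])
            if np.linalg.eigvalsh(omega2)[0] > 1e-10:
                break
        else:
            raise ValueError("perturbation destroyed positive-definiteness")

    g1 = _regenerate(base, omega1, rng)
    g2 = _regenerate(base, omega2, rng)
    return g1, g2, changed


def write_dataset(ds: SyntheticDataset, prefix) -> tuple[Path, Path]:
    """Write counts TSV plus a JSON truth side-car; lossless round-trip."""
    prefix = Path(prefix)
    counts_path = prefix.with_suffix(".counts.tsv")
    truth_path = prefix.with_suffix(".truth.json")
    ds.counts.to_frame().to_csv(counts_path, sep="\t")
    truth = {
        "truth_correlation": ds.truth_correlation.tolist(),
        "truth_precision": ds.truth_precision.tolist(),
        "truth_precision_support":
            ds.truth_precision_support.astype(int).tolist(),
        "mu": ds.mu.tolist(),
        "depth_range": list(ds.depth_range),
        "graph_model": ds.graph_model,
        "seed": ds.seed,
    }
    truth_path.write_text(json.dumps(truth, sort_keys=True))
    return counts_path, truth_path


def read_dataset(prefix) -> SyntheticDataset:
    import pandas as pd

    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t",
                     index_col=0)
    truth = json.loads(prefix.with_suffix(".truth.json").read_text())
    cm = CountMatrix.from_frame(df)
    return SyntheticDataset(
        cm,
        np.asarray(truth["truth_correlation"]),
        np.asarray(truth["truth_precision"]),
        np.asarray(truth["truth_precision_support"], dtype=bool),
        None,
        np.asarray(truth["mu"]),
        tuple(truth["depth_range"]),
        truth["graph_model"],
        truth["seed"],
    )
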