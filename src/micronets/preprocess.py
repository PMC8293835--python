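"""Filtering, zero replacement and normalization of count matrices.

Sequencing counts are compositional: each sample's reads sum to a
technically determined depth, so only ratios between taxa are
informative.  Log-ratio based estimators (clr, proportionality, SparCC)
additionally require strictly positive data, hence the zero-replacement
step.  The normalizations offered here mirror common practice: total
sum scaling (TSS), cumulative sum scaling (CSS), common sum scaling
(COM), rarefaction and the centered log-ratio (clr) transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "FilterSpec",
    "filter_counts",
    "replace_zeros",
    "normalize",
    "clr_transform",
]


@dataclass
class FilterSpec:
    """Taxa/sample filter.

    taxa_rule: ``top_k_frequency`` keeps the k taxa with the largest
    total counts; ``min_total_reads`` keeps taxa whose summed counts
    reach the parameter; ``min_prevalence`` keeps taxa observed
    (count > 0) in at least a fraction ``taxa_param`` of samples.
    ``sample_min_reads`` drops samples with depth below the value
    (inclusive threshold: depth >= sample_min_reads is kept).
    """

    taxa_rule: Optional[str] = None
    taxa_param: float = 0.0
    sample_min_reads: float = 0.0

    def __post_init__(self) -> None:
        if self.taxa_rule is not None:
            if self.taxa_rule not in ("top_k_frequency", "min_total_reads",
                                      "min_prevalence"):
                raise ValueError(f"unknown taxa rule {self.taxa_rule!r}")
            if self.taxa_param <= 0:
                raise ValueError("taxa_param must be > 0")
        if self.sample_min_reads < 0:
            raise ValueError("sample_min_reads must be >= 0")


def filter_counts(counts: CountMatrix, spec: FilterSpec) -> CountMatrix:
    """Apply sample filtering first (on original depths), then taxa filtering."""
    if counts.n_samples == 0 or counts.n_taxa == 0:
        raise ValueError("empty count matrix")

    keep_samples = counts.depths >= spec.sample_min_reads
    if not np.any(keep_samples):
        raise ValueError(
            f"sample_min_reads={spec.sample_min_reads} removes all "
            f"{counts.n_samples} samples"
        )
    values = counts.values[keep_samples]
    sample_ids = [s for s, k in zip(counts.sample_ids, keep_samples) if k]

    taxon_ids = list(counts.taxon_ids)
    if spec.taxa_rule is not None:
        totals = values.sum(axis=0)
        p = len(taxon_ids)
        if spec.taxa_rule == "top_k_frequency":
            k = int(spec.taxa_param)
            if k > p:
                raise ValueError(f"requested top {k} taxa but only {p} "
                                 "taxa are available")
            # tie-break deterministically by ascending taxon label
            order = sorted(range(p), key=lambda i: (-totals[i], taxon_ids[i]))
            keep_idx = sorted(order[:k])
        elif spec.taxa_rule == "min_total_reads":
            keep_idx = [i for i in range(p) if totals[i] >= spec.taxa_param]
        else:  # min_prevalence
            prev = (values > 0).mean(axis=0)
            keep_idx = [i for i in range(p) if prev[i] >= spec.taxa_param]
        values = values[:, keep_idx]
        taxon_ids = [taxon_ids[i] for i in keep_idx]

    return CountMatrix(values, sample_ids, taxon_ids)


def _proportions(counts: CountMatrix) -> np.ndarray:
    depths = counts.depths
    zero_rows = np.nonzero(depths == 0)[0]
    if zero_rows.size:
        raise ValueError(
            f"sample {counts.sample_ids[zero_rows[0]]!r} contains only zeros"
        )
    return counts.values / depths[:, None]


def replace_zeros(
    counts: CountMatrix,
    method: str = "multiplicative",
    delta: Optional[float] = None,
    alpha: float = 0.5,
) -> NormalizedMatrix:
    """Replace zero counts and return strictly positive proportions.

    multiplicative: rows are converted to proportions, every zero cell
    is imputed with ``delta`` and the non-zero cells of a row with Z_k
    zeros are shrunk by (1 - Z_k * delta), preserving the unit sum and
    the ratios between non-zero parts.  ``delta`` defaults to 0.1 times
    the smallest observed non-zero proportion.

    bayes_mult: posterior-mean proportions under a Dirichlet(alpha)
    prior, pi_i = (c_i + alpha_i) / (m + sum(alpha)); zero cells take
    their posterior mean while non-zero cells are rescaled
    multiplicatively so each row stays on the simplex.
    """
    if method not in ("multiplicative", "bayes_mult"):
        raise ValueError(f"unknown zero-replacement method {method!r}")
    props = _proportions(counts)
    n, p = props.shape
    is_zero = counts.values == 0

    if method == "multiplicative":
        if delta is None:
            nz = props[props > 0]
            delta = 0.1 * nz.min()
        if not (0 < delta < 1.0 / p):
            raise ValueError(
                f"delta={delta} must lie in (0, 1/p)={1.0 / p:.4g} to keep "
                "rows on the simplex"
            )
        out = props.copy()
        z_per_row = is_zero.sum(axis=1)
        shrink = 1.0 - z_per_row * delta
        out *= shrink[:, None]
        out[is_zero] = delta
    else:
        alpha_vec = np.full(p, float(alpha))
        post = (counts.values + alpha_vec) / (
            counts.depths + alpha_vec.sum())[:, None]
        out = props.copy()
        out[is_zero] = post[is_zero]
        # rescale originally non-zero cells so each row sums to one
        for k in range(n):
            zmask = is_zero[k]
            if not zmask.any():
                continue
            imputed = out[k, zmask].sum()
            out[k, ~zmask] *= (1.0 - imputed)
    return NormalizedMatrix(out, counts.sample_ids, counts.taxon_ids,
                            scale="simplex", method="proportions",
                            zero_method=method)


def clr_transform(values: np.ndarray) -> np.ndarray:
    """Row-wise centered log-ratio: log(x_i / g(x)) with g the geometric mean."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("clr requires strictly positive entries; apply "
                         "replace_zeros first")
    logs = np.log(values)
    return logs - logs.mean(axis=1, keepdims=True)


def normalize(
    counts: CountMatrix,
    method: str = "TSS",
    css_quantile: float = 0.5,
    rarefy_level: Optional[int] = None,
    seed: Optional[int] = None,
) -> NormalizedMatrix:
    """Normalize counts across samples.

    TSS divides each sample by its depth; CSS divides by the cumulative
    sum of counts up to a quantile (scaled by the median of those sums
    across samples, so the output remains on a count-like scale); COM
    rescales every sample to the minimum depth; rarefy subsamples reads
    without replacement down to a common level; clr applies the
    centered log-ratio transform to the sample proportions.
    """
    ids = (counts.sample_ids, counts.taxon_ids)
    if method == "TSS":
        return NormalizedMatrix(_proportions(counts), *ids, scale="simplex",
                                method="TSS")
    if method == "clr":
        if np.any(counts.values <= 0):
            raise ValueError("clr requires strictly positive input; run "
                             "replace_zeros first")
        return NormalizedMatrix(clr_transform(counts.values), *ids,
                                scale="clr-log", method="clr")
    if method == "COM":
        depths = counts.depths
        m_min = depths.min()
        out = counts.values * (m_min / depths)[:, None]
        return NormalizedMatrix(out, *ids, scale="counts", method="COM")
    if method == "CSS":
        # per-sample cumulative sum of counts up to the chosen quantile
        sums = np.empty(counts.n_samples)
        for k, row in enumerate(counts.values):
            nz = row[row > 0]
            if nz.size == 0:
                raise ValueError(
                    f"sample {counts.sample_ids[k]!r} contains only zeros")
            q = np.quantile(nz, css_quantile)
            sums[k] = row[row <= q].sum()
            if sums[k] == 0:
                sums[k] = row.sum()
        scale_const = np.median(sums)
        out = counts.values / sums[:, None] * scale_const
        return NormalizedMatrix(out, *ids, scale="counts", method="CSS")
    if method == "rarefy":
        if seed is None:
            raise ValueError("rarefy requires a seed")
        vals = counts.values
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("rarefy requires integer counts")
        vals = np.round(vals).astype(np.int64)
        depths = vals.sum(axis=1)
        level = int(rarefy_level) if rarefy_level is not None \
            else int(depths.min())
        low = np.nonzero(depths < level)[0]
        if low.size:
            raise ValueError(
                f"rarefaction level {level} exceeds depth of sample "
                f"{counts.sample_ids[low[0]]!r} ({depths[low[0]]})")
        rng = np.random.default_rng(seed)
        out = np.empty_like(vals)
        for k, row in enumerate(vals):
            out[k] = rng.multivariate_hypergeometric(row, level)
        return NormalizedMatrix(out.astype(float), *ids, scale="counts",
                                method="rarefy")
    raise ValueError(f"unknown normalization method {method!r}")
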