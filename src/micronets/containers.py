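"""Core data containers shared across the network-construction workflow.

Count matrices hold raw sequencing reads (samples x taxa); normalized
matrices live either on the simplex (rows sum to one) or in clr space
(rows sum to zero); association matrices are symmetric taxon-by-taxon
estimates; adjacency bundles are the numerical representation of a
network (sparsified association plus paired dissimilarity/similarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "AssociationMatrix",
    "SparsifiedAssociation",
    "AdjacencyBundle",
    "SampleDissimilarity",
    "GroupDesign",
]

_ATOL = 1e-9


def _check_labels(labels: Sequence[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: labels must be unique")
    return labels


@dataclass
class CountMatrix:
    """Samples x taxa matrix of non-negative abundances.

    ``depths`` (per-sample sequencing depth m) is derived from the row
    sums and kept consistent with ``values``.
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.values < 0):
            k, i = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at sample {k} ({self.sample_ids[k]!r}), "
                f"taxon {i}"
            )
        n, p = self.values.shape
        self.sample_ids = _check_labels(self.sample_ids, n, "sample_ids")
        self.taxon_ids = _check_labels(self.taxon_ids, p, "taxon_ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total reads m^(k)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))


@dataclass
class NormalizedMatrix:
    """Normalized abundance matrix.

    ``scale`` records where the rows live: ``simplex`` (positive,
    unit-sum), ``counts`` (rescaled count scale, e.g. CSS/COM/rarefy)
    or ``clr-log`` (real-valued, zero-sum rows).
    """

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    scale: str
    method: str = "none"
    zero_method: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        self.sample_ids = _check_labels(self.sample_ids, n, "sample_ids")
        self.taxon_ids = _check_labels(self.taxon_ids, p, "taxon_ids")
        if self.scale not in ("simplex", "counts", "clr-log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        rs = self.values.sum(axis=1)
        if self.scale == "simplex":
            if np.any(self.values <= 0):
                raise ValueError("simplex-scale matrix must be strictly "
                                 "positive (apply zero replacement)")
            if np.any(np.abs(rs - 1.0) > _ATOL):
                raise ValueError("simplex-scale rows must sum to 1")
        elif self.scale == "clr-log":
            if np.any(np.abs(rs) > 1e-6 * max(1.0, np.abs(self.values).max())):
                raise ValueError("clr-scale rows must sum to 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.taxon_ids)


# association measures whose entries are genuine correlations; SparCC may
# step outside [-1, 1] and is flagged downstream.
CORRELATION_MEASURES = ("pearson", "spearman", "bicor")


@dataclass
class AssociationMatrix:
    """Symmetric p x p association estimate r_ij with a measure tag."""

    values: np.ndarray
    taxon_ids: list[str]
    measure: str
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("association matrix must be square")
        self.taxon_ids = _check_labels(self.taxon_ids, p, "taxon_ids")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
            raise ValueError("association matrix must be symmetric")
        # enforce exact symmetry (floating-point estimators may differ in
        # the last ulp between the two triangles)
        iu = np.triu_indices(p, 1)
        self.values[(iu[1], iu[0])] = self.values[iu]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids,
                            columns=self.taxon_ids)


@dataclass
class SparsifiedAssociation:
    """Association matrix after edge selection; unselected entries are 0."""

    values: np.ndarray
    taxon_ids: list[str]
    method: str
    measure: str = "unknown"
    n_samples: int = 0
    pvalues: Optional[np.ndarray] = None
    adjusted_pvalues: Optional[np.ndarray] = None
    alpha: Optional[float] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def selected(self) -> np.ndarray:
        sel = self.values != 0.0
        np.fill_diagonal(sel, False)
        return sel


@dataclass
class AdjacencyBundle:
    """Numerical representation of one network.

    ``dissimilarity`` feeds shortest-path metrics, ``similarity`` feeds
    connection-strength metrics (degree, eigenvector, modularity).  For
    weighted bundles s = 1 - d holds on selected edges; unweighted
    bundles carry the 0/1 edge indicator as similarity and unit
    dissimilarity on edges.
    """

    dissimilarity: np.ndarray
    similarity: np.ndarray
    edge_indicator: np.ndarray
    node_ids: list[str]
    diss_mode: str
    weighted: bool = True
    soft_power: Optional[float] = None
    association: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dissimilarity = np.asarray(self.dissimilarity, dtype=float)
        self.similarity = np.asarray(self.similarity, dtype=float)
        self.edge_indicator = np.asarray(self.edge_indicator, dtype=bool)
        np.fill_diagonal(self.similarity, 0.0)
        np.fill_diagonal(self.edge_indicator, False)

    @property
    def n_nodes(self) -> int:
        return self.similarity.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.edge_indicator.sum()) // 2

    def to_graph(self):
        """Undirected networkx graph with similarity/dissimilarity weights."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        ii, jj = np.nonzero(np.triu(self.edge_indicator, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(
                self.node_ids[i], self.node_ids[j],
                similarity=float(self.similarity[i, j]),
                dissimilarity=float(self.dissimilarity[i, j]),
                association=(float(self.association[i, j])
                             if self.association is not None else None),
            )
        return g


@dataclass
class SampleDissimilarity:
    """n x n symmetric dissimilarity between samples (subjects)."""

    values: np.ndarray
    sample_ids: list[str]
    method: str
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        self.sample_ids = _check_labels(self.sample_ids, n, "sample_ids")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-9:
            raise ValueError("dissimilarity must be symmetric")
        np.fill_diagonal(self.values, 0.0)
        if np.any(self.values < -1e-12):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class GroupDesign:
    """Binary two-group design over samples."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        uniq = np.unique(self.labels)
        if len(uniq) != 2:
            raise ValueError("group design needs exactly two distinct labels")
        self._groups = uniq
        if self.n1 < 3 or self.n2 < 3:
            raise ValueError("each group needs at least 3 samples")

    @property
    def mask1(self) -> np.ndarray:
        return self.labels == self._groups[0]

    @property
    def mask2(self) -> np.ndarray:
        return self.labels == self._groups[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == self._groups[0]))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == self._groups[1]))

    @property
    def group_names(self) -> tuple[str, str]:
        return str(self._groups[0]), str(self._groups[1])
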