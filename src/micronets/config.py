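"""Workflow configuration: registered options, YAML parsing, and the
compositional-awareness check.

A configuration describes one end-to-end network construction:
filtering, zero handling, normalization, association measure,
sparsification and the adjacency transform, plus the analysis and
comparison settings.  Combinations that ignore the compositional
structure of sequencing counts (e.g. Pearson correlation on raw
proportions) are permitted but trigger a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .preprocess import FilterSpec

__all__ = ["WorkflowConfig", "load_config"]

ZERO_METHODS = (None, "multiplicative", "bayes_mult")
NORM_METHODS = (None, "TSS", "CSS", "COM", "rarefy", "clr")
MEASURES = ("pearson", "spearman", "bicor", "sparcc", "rho", "nbhd_partial")
SPARSIFY_METHODS = ("threshold", "ttest", "bootstrap", "none", "soft")
DISS_MODES = ("unsigned", "signed", "signedPos")
CLUSTER_METHODS = ("greedy_modularity", "hierarchical", "edge_betweenness")
HUB_METHODS = ("empirical_quantile", "lognormal_quantile")
ADJUST_METHODS = ("none", "bonferroni", "holm", "BH", "BY", "adaptiveBH")
DISSIMILARITY_METHODS = ("euclidean", "bray_curtis", "kld", "jeffrey",
                         "jensen_shannon", "comp_kld", "aitchison")

# measures that handle compositionality internally, and normalizations
# that make traditional correlations compositionally aware
_AWARE_MEASURES = ("sparcc", "rho", "nbhd_partial")


@dataclass
class WorkflowConfig:
    """Resolved parameters for one construct/analyze/compare run."""

    # preprocess
    filter: Optional[FilterSpec] = None
    zero_method: Optional[str] = "multiplicative"
    zero_params: dict = field(default_factory=dict)
    norm_method: Optional[str] = "clr"
    norm_params: dict = field(default_factory=dict)
    # association
    measure: str = "pearson"
    measure_params: dict = field(default_factory=dict)
    # sparsification + adjacency
    sparsify_method: str = "threshold"
    threshold: float = 0.3
    alpha: float = 0.05
    adjust: str = "adaptiveBH"
    sparsify_params: dict = field(default_factory=dict)
    diss_mode: str = "signed"
    weighted: bool = True
    include_negatives: bool = True
    soft_power: Optional[float] = None
    # analysis
    cluster_method: str = "greedy_modularity"
    cluster_params: dict = field(default_factory=dict)
    hub_measures: Sequence[str] = ("eigenvector",)
    hub_method: str = "empirical_quantile"
    hub_q: float = 0.95
    # comparison
    n_perm: int = 1000
    compare_alpha: float = 0.05
    compare_adjust: str = "adaptiveBH"
    seed: Optional[int] = None
    # sample networks
    dissimilarity: str = "aitchison"
    knn_k: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.zero_method not in ZERO_METHODS:
            raise ValueError(f"unknown zero method {self.zero_method!r}")
        if self.norm_method not in NORM_METHODS:
            raise ValueError(f"unknown normalization {self.norm_method!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown association measure {self.measure!r}")
        if self.sparsify_method not in SPARSIFY_METHODS:
            raise ValueError(
                f"unknown sparsification {self.sparsify_method!r}")
        if self.diss_mode not in DISS_MODES:
            raise ValueError(f"unknown dissimilarity mode "
                             f"{self.diss_mode!r}")
        if self.cluster_method not in CLUSTER_METHODS:
            raise ValueError(f"unknown cluster method "
                             f"{self.cluster_method!r}")
        if self.hub_method not in HUB_METHODS:
            raise ValueError(f"unknown hub method {self.hub_method!r}")
        if self.adjust not in ADJUST_METHODS or \
                self.compare_adjust not in ADJUST_METHODS:
            raise ValueError("unknown p-value adjustment method")
        if self.dissimilarity not in DISSIMILARITY_METHODS:
            raise ValueError(f"unknown sample dissimilarity "
                             f"{self.dissimilarity!r}")
        if self.measure in ("rho", "nbhd_partial") and \
                self.zero_method is None:
            warnings.warn(
                f"{self.measure} requires strictly positive data; zeros "
                "will raise unless the input has none (set zero_method)",
                RuntimeWarning)
        if not self.is_compositionally_aware():
            warnings.warn(
                f"combination measure={self.measure!r} with "
                f"normalization={self.norm_method!r} is not "
                "compositionally aware", RuntimeWarning)

    def is_compositionally_aware(self) -> bool:
        if self.measure in _AWARE_MEASURES:
            return True
        return self.norm_method == "clr"

    def without_filter(self) -> "WorkflowConfig":
        if self.filter is None:
            return self
        cfg = WorkflowConfig(**{**self._as_kwargs(), "filter": None})
        return cfg

    def _as_kwargs(self) -> dict:
        d = asdict(self)
        if self.filter is not None:
            d["filter"] = self.filter
        return d

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hub_measures"] = list(self.hub_measures)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "WorkflowConfig":
        doc = dict(doc or {})
        kwargs: dict = {}
        pre = doc.pop("preprocess", {})
        if "filter" in pre and pre["filter"]:
            kwargs["filter"] = FilterSpec(**pre["filter"])
        for key in ("zero_method", "zero_params", "norm_method",
                    "norm_params"):
            if key in pre:
                kwargs[key] = pre[key]
        assoc = doc.pop("association", {})
        if "measure" in assoc:
            kwargs["measure"] = assoc["measure"]
        if "params" in assoc:
            kwargs["measure_params"] = assoc["params"]
        sp = doc.pop("sparsify", {})
        for src, dst in (("method", "sparsify_method"),
                         ("threshold", "threshold"), ("alpha", "alpha"),
                         ("adjust", "adjust"), ("params", "sparsify_params")):
            if src in sp:
                kwargs[dst] = sp[src]
        adj = doc.pop("adjacency", {})
        for key in ("diss_mode", "weighted", "include_negatives",
                    "soft_power"):
            if key in adj:
                kwargs[key] = adj[key]
        ana = doc.pop("analysis", {})
        for key in ("cluster_method", "cluster_params", "hub_measures",
                    "hub_method", "hub_q"):
            if key in ana:
                kwargs[key] = ana[key]
        comp = doc.pop("compare", {})
        for src, dst in (("n_perm", "n_perm"), ("alpha", "compare_alpha"),
                         ("adjust", "compare_adjust"), ("seed", "seed")):
            if src in comp:
                kwargs[dst] = comp[src]
        sam = doc.pop("samplenet", {})
        for src, dst in (("dissimilarity", "dissimilarity"), ("k", "knn_k")):
            if src in sam:
                kwargs[dst] = sam[src]
        # flat keys override/extend
        for key, val in doc.items():
            kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)


def load_config(path=None, **overrides) -> WorkflowConfig:
    if path is not None:
        cfg = WorkflowConfig.from_yaml(path)
        if overrides:
            kwargs = cfg._as_kwargs()
            kwargs.update(overrides)
            cfg = WorkflowConfig(**kwargs)
        return cfg
    return WorkflowConfig(**overrides)
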