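"""Shared helpers for building test networks."""

import numpy as np

from micronets import AdjacencyBundle


def bundle_from_sim(sim, weighted=True, diss=None):
    """AdjacencyBundle from a raw similarity matrix."""
    sim = np.asarray(sim, dtype=float)
    edge = sim > 0
    np.fill_diagonal(edge, False)
    if diss is None:
        diss = np.where(edge, 1.0 - sim, 0.0)
    ids = [f"n{i}" for i in range(sim.shape[0])]
    return AdjacencyBundle(diss, np.where(edge, sim, 0.0), edge, ids,
                           diss_mode="signed", weighted=weighted)


def bundle_unweighted(edge):
    """Unit-weight bundle from a boolean adjacency matrix."""
    edge = np.asarray(edge, dtype=bool)
    np.fill_diagonal(edge, False)
    ids = [f"n{i}" for i in range(edge.shape[0])]
    return AdjacencyBundle(edge.astype(float), edge.astype(float), edge,
                           ids, diss_mode="signed", weighted=False)
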