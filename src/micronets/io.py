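"""Reading and writing the workflow's file formats.

Count tables come in as TSV/CSV (samples in rows by default, an
orientation flag transposes) or BIOM (JSON or HDF5 dialect).
Association matrices round-trip through labeled square TSV so that
externally estimated matrices can enter the pipeline.  Networks are
exported as edge-list TSV (bit-exact round-trip) and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import AdjacencyBundle, AssociationMatrix, CountMatrix

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_association",
    "write_association",
    "write_edge_list",
    "read_edge_list",
    "bundle_from_edge_list",
    "write_graphml",
    "write_json",
]


def _validate_counts_frame(df: pd.DataFrame) -> CountMatrix:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample label {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate taxon label {dup!r}")
    vals = df.to_numpy(dtype=float)
    neg = np.argwhere(vals < 0)
    if neg.size:
        k, i = neg[0]
        raise ValueError(f"negative count at sample {df.index[k]!r}, "
                         f"taxon {df.columns[i]!r}")
    return CountMatrix(vals, list(df.index.astype(str)),
                       list(df.columns.astype(str)))


def _read_biom_json(path: Path) -> pd.DataFrame:
    doc = json.loads(path.read_text())
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = doc["shape"]
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    # BIOM stores observations (taxa) x samples; transpose to samples x taxa
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def _read_biom_hdf5(path: Path) -> pd.DataFrame:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        taxa = [t.decode() if isinstance(t, bytes) else str(t)
                for t in f["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = csr_matrix((grp["data"][:], grp["indices"][:],
                          grp["indptr"][:]),
                         shape=(len(taxa), len(samples))).toarray()
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def read_count_table(path, format: Optional[str] = None,
                     orientation: str = "samples_by_taxa") -> CountMatrix:
    """Read a count table; ``orientation='taxa_by_samples'`` transposes."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".biom": "biom"}.get(suffix, "tsv")
    if format == "biom":
        try:
            df = _read_biom_hdf5(path)
        except (OSError, KeyError):
            df = _read_biom_json(path)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            dup = next(h for h in header if header.count(h) > 1)
            raise ValueError(f"duplicate taxon label {dup!r}")
        df = pd.read_csv(path, sep=sep, index_col=0)
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValueError(f"unknown orientation {orientation!r}")
    return _validate_counts_frame(df)


def write_count_table(counts: CountMatrix, path,
                      format: str = "tsv") -> Path:
    path = Path(path)
    sep = "\t" if format == "tsv" else ","
    counts.to_frame().to_csv(path, sep=sep)
    return path


def write_association(assoc: AssociationMatrix, path) -> Path:
    """Square labeled TSV with full-precision (round-trippable) floats."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(assoc.taxon_ids) + "\n")
        for i, tid in enumerate(assoc.taxon_ids):
            row = "\t".join(repr(float(v)) for v in assoc.values[i])
            fh.write(f"{tid}\t{row}\n")
    return path


def read_association(path, measure: str = "external",
                     n_samples: int = 0) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    vals = df.to_numpy(dtype=float)
    return AssociationMatrix(vals, list(df.columns.astype(str)),
                             measure=measure, n_samples=n_samples)


EDGE_LIST_COLUMNS = ("taxon_a", "taxon_b", "association", "similarity",
                     "dissimilarity")


def write_edge_list(bundle: AdjacencyBundle, path) -> Path:
    """Edge-list TSV; floats are written with shortest round-trip repr so
    reading the file back reproduces the values bit-exactly."""
    path = Path(path)
    ii, jj = np.nonzero(np.triu(bundle.edge_indicator, 1))
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_LIST_COLUMNS) + "\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            assoc = (bundle.association[i, j]
                     if bundle.association is not None else float("nan"))
            fh.write(f"{bundle.node_ids[i]}\t{bundle.node_ids[j]}\t"
                     f"{repr(float(assoc))}\t"
                     f"{repr(float(bundle.similarity[i, j]))}\t"
                     f"{repr(float(bundle.dissimilarity[i, j]))}\n")
    return path


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip",
                       dtype={"taxon_a": str, "taxon_b": str})


def bundle_from_edge_list(df: pd.DataFrame, node_ids: list[str],
                          diss_mode: str = "signed",
                          weighted: bool = True) -> AdjacencyBundle:
    p = len(node_ids)
    pos = {nid: i for i, nid in enumerate(node_ids)}
    diss = np.zeros((p, p))
    sim = np.zeros((p, p))
    assoc = np.zeros((p, p))
    edge = np.zeros((p, p), dtype=bool)
    for row in df.itertuples(index=False):
        i, j = pos[row.taxon_a], pos[row.taxon_b]
        edge[i, j] = edge[j, i] = True
        diss[i, j] = diss[j, i] = row.dissimilarity
        sim[i, j] = sim[j, i] = row.similarity
        assoc[i, j] = assoc[j, i] = row.association
    return AdjacencyBundle(diss, sim, edge, list(node_ids),
                           diss_mode=diss_mode, weighted=weighted,
                           association=assoc)


def write_graphml(bundle: AdjacencyBundle, path) -> Path:
    import networkx as nx

    g = bundle.to_graph()
    for _, _, data in g.edges(data=True):
        if data.get("association") is None:
            data.pop("association", None)
    nx.write_graphml(g, str(path))
    return Path(path)


def write_json(obj: dict, path) -> Path:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1,
                               default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
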