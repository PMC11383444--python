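"""Sparse brain-graph construction from connectivity matrices.

The graph kept for message passing is a top-k sparsification of a
connectivity matrix: each node keeps its k strongest supra-threshold
neighbors and the edge set is the union of those selections (an edge
survives if either endpoint picked it), so degrees may exceed k.  Node
features are connectivity-profile rows: each node's feature vector is the
concatenation of its FC row and its normalized-SC row for whichever
modalities are active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ConnectivityMatrix

__all__ = ["BrainGraph", "build_adjacency", "build_node_features", "build_graph"]


@dataclass
class BrainGraph:
    """Adjacency (no self-loops stored) plus node features for one subject."""

    adjacency: np.ndarray  # Q x Q, symmetric, zero diagonal
    node_features: np.ndarray  # Q x d0
    roi_ids: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def build_adjacency(
    conn: ConnectivityMatrix | np.ndarray,
    k: int = 30,
    threshold: float = 0.001,
    binary: bool = False,
    symmetrize: str = "union",
) -> np.ndarray:
    """Top-k supra-threshold sparsification of a connectivity matrix.

    Per node, the k largest off-diagonal entries strictly above ``threshold``
    are selected (fewer if fewer exist — sparse SC rows simply keep whatever
    connections they have).  ``symmetrize="union"`` keeps an edge if either
    endpoint selected it; ``"intersection"`` requires both.  Edge weights are
    the connectivity values unless ``binary`` is set.
    """
    values = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    q = values.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if symmetrize not in ("union", "intersection"):
        raise ValueError("symmetrize must be 'union' or 'intersection'")

    w = values.copy()
    np.fill_diagonal(w, -np.inf)
    selected = np.zeros((q, q), dtype=bool)
    for i in range(q):
        row = w[i]
        cand = np.flatnonzero(row > threshold)
        if cand.size == 0:
            continue
        if cand.size > k:
            cand = cand[np.argsort(row[cand])[::-1][:k]]
        selected[i, cand] = True

    keep = (selected | selected.T) if symmetrize == "union" else (selected & selected.T)
    adj = np.where(keep, values, 0.0)
    if binary:
        adj = keep.astype(float)
    adj = np.maximum(adj, adj.T)  # weights symmetric by input symmetry; guard fp
    np.fill_diagonal(adj, 0.0)
    return adj


def build_node_features(
    fc: ConnectivityMatrix | None,
    sc: ConnectivityMatrix | None,
    modalities: tuple[str, ...] = ("FC", "SC"),
) -> np.ndarray:
    """Connectivity-profile node features.

    Node q's feature vector concatenates its FC row and its normalized-SC
    row, restricted to the active connectivity modalities; d0 = 2Q for both,
    Q for a single-modality ablation.  Diagonal entries are kept as-is.
    """
    blocks = []
    if "FC" in modalities:
        if fc is None:
            raise ValueError("FC requested but no FC matrix given")
        blocks.append(fc.values)
    if "SC" in modalities:
        if sc is None:
            raise ValueError("SC requested but no SC matrix given")
        blocks.append(sc.values)
    if not blocks:
        raise ValueError("at least one connectivity modality must be active")
    if len(blocks) == 2 and blocks[0].shape[0] != blocks[1].shape[0]:
        raise ValueError("FC and SC disagree on ROI count")
    return np.concatenate(blocks, axis=1)


def build_graph(
    fc: ConnectivityMatrix | None,
    sc: ConnectivityMatrix | None,
    modalities: tuple[str, ...] = ("FC", "SC"),
    k: int = 30,
    threshold: float = 0.001,
    binary: bool = False,
    roi_ids: list[str] | None = None,
) -> BrainGraph:
    """Build the subject graph: FC defines the topology when it is active
    (the multimodal setting); SC defines it for SC-only runs."""
    conn_modalities = tuple(m for m in modalities if m in ("FC", "SC"))
    if "FC" in conn_modalities:
        base = fc
    elif "SC" in conn_modalities:
        base = sc
    else:
        raise ValueError("no connectivity modality active")
    if base is None:
        raise ValueError("the graph-defining connectivity matrix is missing")
    adj = build_adjacency(base, k=k, threshold=threshold, binary=binary)
    feats = build_node_features(fc, sc, modalities=conn_modalities)
    return BrainGraph(adjacency=adj, node_features=feats, roi_ids=roi_ids)
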