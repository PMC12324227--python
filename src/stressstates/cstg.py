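"""Cell-state transition graph (CSTG) construction.

The CSTG is an undirected composite graph over cluster centroids combining
two complementary edge sets: (a) dendrogram edges — processing the
Ward-linkage merges in height order, each merge of two subtrees contributes
the edge between their closest centroid pair, giving a k - 1 edge spanning
tree that respects the hierarchy; and (b) nearest-neighbour edges — each
cluster linked to its two nearest centroids (Euclidean).  Edges present in
both sets are tagged "both".  The composite graph is simple, connected (it
contains the spanning tree) and has minimum degree >= 2 (every node keeps
its two NN links).  Transitions are putative: the graph is undirected and
carries no rates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .states import Dendrogram, StateModel

logger = logging.getLogger(__name__)


class CSTGError(ValueError):
    pass


def dendrogram_edges(
    dendrogram: Dendrogram, centroids: pd.DataFrame
) -> list[tuple[int, int]]:
    """One edge per dendrogram merge: the closest centroid pair across the
    two merged subtrees, ties broken by lexicographic (smaller, larger)
    cluster-id pair.  Yields exactly k - 1 edges forming a spanning tree."""
    ids = list(centroids.index)
    n = len(ids)
    X = centroids.to_numpy(dtype=float)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}  # positions
    Z = dendrogram.linkage_matrix
    order = np.argsort(Z[:, 2], kind="stable")
    edges: list[tuple[int, int]] = []
    for mi in order:
        left, right = int(Z[mi, 0]), int(Z[mi, 1])
        lm, rm = members[left], members[right]
        d = cdist(X[lm], X[rm])
        best = None
        for li, l in enumerate(lm):
            for ri, r in enumerate(rm):
                pair = tuple(sorted((ids[l], ids[r])))
                key = (d[li, ri], pair)
                if best is None or key < best:
                    best = key
        edges.append(best[1])
        members[n + mi] = lm + rm
    return edges


def knn_edges(centroids: pd.DataFrame, k_nn: int = 2) -> list[tuple[int, int]]:
    """Undirected edges from each cluster to its k_nn nearest centroids;
    distance ties prefer the lower cluster id; duplicates collapsed."""
    ids = list(centroids.index)
    if len(ids) < k_nn + 1:
        raise CSTGError(f"need more than {k_nn} clusters")
    X = centroids.to_numpy(dtype=float)
    D = cdist(X, X)
    edges: set[tuple[int, int]] = set()
    for i in range(len(ids)):
        order = sorted(
            (j for j in range(len(ids)) if j != i), key=lambda j: (D[i, j], ids[j])
        )
        for j in order[:k_nn]:
            edges.add(tuple(sorted((ids[i], ids[j]))))
    return sorted(edges)


def build_cstg(
    dend_edges: list[tuple[int, int]],
    nn_edges: list[tuple[int, int]],
    centroids: pd.DataFrame,
    groups: pd.Series | None = None,
    sizes: pd.Series | None = None,
) -> nx.Graph:
    """Compose the two edge sets into the CSTG.

    Node attributes: phenotypic ``group``, ``size`` (cell count) and the
    centroid coordinates.  Edge attributes: ``source`` in
    {dendrogram, knn, both} and the centroid Euclidean ``distance``.
    """
    ids = set(centroids.index)
    for u, v in list(dend_edges) + list(nn_edges):
        if u not in ids or v not in ids:
            raise CSTGError(f"edge ({u}, {v}) references unknown cluster")
    g = nx.Graph()
    X = centroids.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(centroids.index)}
    for c in centroids.index:
        g.add_node(
            c,
            group=str(groups.loc[c]) if groups is not None else "",
            size=int(sizes.loc[c]) if sizes is not None else 0,
            centroid=",".join(f"{x:.6g}" for x in X[pos[c]]),
        )
    dset = {tuple(sorted(e)) for e in dend_edges}
    kset = {tuple(sorted(e)) for e in nn_edges}
    for u, v in sorted(dset | kset):
        if u == v:
            continue
        source = "both" if (u, v) in dset and (u, v) in kset else (
            "dendrogram" if (u, v) in dset else "knn"
        )
        g.add_edge(
            u, v,
            source=source,
            distance=float(np.linalg.norm(X[pos[u]] - X[pos[v]])),
        )
    if not nx.is_connected(g):
        raise CSTGError("composite graph is not connected")
    return g


def cstg_from_model(
    model: StateModel,
    dendrogram: Dendrogram,
    groups: pd.Series | None = None,
    k_nn: int = 2,
) -> nx.Graph:
    """Convenience wrapper: dendrogram + NN edges from a fitted state model."""
    de = dendrogram_edges(dendrogram, model.centroids)
    ke = knn_edges(model.centroids, k_nn=k_nn)
    return build_cstg(de, ke, model.centroids, groups, model.cluster_sizes())


def layout(graph: nx.Graph, seed: int = 0) -> dict:
    """Deterministic force-directed (Fruchterman-Reingold) layout."""
    return nx.spring_layout(graph, seed=seed)


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def export_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, **data} for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
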