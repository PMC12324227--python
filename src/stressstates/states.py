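"""Clustering cells into stress states and phenotypic groups.

Cells live in an 8-dimensional space of standardised stress-pathway scores
(fixed pathway order APO, AUT, DDR, HPX, HSR, OSR, SEN, UPR).  States are
found by k-means (default k = 25, chosen to balance granularity and
interpretability; a scan over k with silhouette, Calinski-Harabasz and
Davies-Bouldin indices supports the choice).  Cluster centroids are then
organised by Ward/Euclidean agglomeration, and cutting that dendrogram
yields a small number of phenotypic groups (default 5), labelled with Roman
numerals in ascending order of mean total pathway activation so that Group
I is the basal state.

Cluster summaries report, per (cluster, pathway), the mean score and the
fraction of member cells whose score exceeds the global mean + 1 SD for
that pathway — the quantities shown in the dot-heatmap rendering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster, leaves_list
from sklearn.cluster import KMeans
from sklearn.metrics import (
    silhouette_score,
    calinski_harabasz_score,
    davies_bouldin_score,
)

logger = logging.getLogger(__name__)


class StateError(ValueError):
    pass


def _roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    if i < len(numerals):
        return numerals[i]
    return f"G{i + 1}"


def _as_array(scores) -> tuple[np.ndarray, pd.Index, list[str]]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), scores.index, list(scores.columns)
    arr = np.asarray(scores, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0]), [f"dim{i}" for i in range(arr.shape[1])]


@dataclass
class StateModel:
    """A fitted k-means partition of cells in pathway-score space."""

    k: int
    centroids: pd.DataFrame          # k × n_srps, indexed by cluster id
    assignments: pd.Series           # cell id -> cluster id
    inertia: float
    seed: int

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(
            self.centroids.index, fill_value=0
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "inertia": self.inertia,
            "srps": list(self.centroids.columns),
            "centroids": self.centroids.to_numpy().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def scan_k(
    scores, k_range=range(10, 101), seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Fit k-means over a range of k and report cluster-quality indices.

    Silhouette and Calinski-Harabasz are better-is-larger; Davies-Bouldin
    is better-is-smaller.
    """
    X, _, _ = _as_array(scores)
    rows = []
    for k in k_range:
        if k >= X.shape[0]:
            raise StateError(f"k = {k} >= {X.shape[0]} cells")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        lab = km.labels_
        rows.append(
            {
                "k": k,
                "inertia": km.inertia_,
                "silhouette": silhouette_score(X, lab),
                "calinski_harabasz": calinski_harabasz_score(X, lab),
                "davies_bouldin": davies_bouldin_score(X, lab),
            }
        )
    return pd.DataFrame(rows)


def fit_states(scores, k: int = 25, seed: int = 0, n_init: int = 10) -> StateModel:
    """k-means with k-means++ initialisation, best of ``n_init`` restarts."""
    X, cells, srps = _as_array(scores)
    if X.shape[0] <= k:
        raise StateError(f"need more than k = {k} cells, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    centroids = pd.DataFrame(
        km.cluster_centers_, index=pd.RangeIndex(k, name="cluster"), columns=srps
    )
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=pd.Series(km.labels_, index=cells, name="cluster"),
        inertia=float(km.inertia_),
        seed=seed,
    )


@dataclass
class ClusterSummary:
    """Per-(cluster, pathway) mean score and fraction of high-scoring cells."""

    mean_score: pd.DataFrame   # clusters × srps
    frac_high: pd.DataFrame    # clusters × srps, against global mean + 1 SD
    sizes: pd.Series
    groups: pd.Series | None = None   # cluster -> phenotypic group label


def summarize_clusters(model: StateModel, scores) -> ClusterSummary:
    """Mean score per (cluster, pathway) and the fraction of member cells
    above the global per-pathway mean + 1 SD (population SD over all cells)."""
    X, cells, srps = _as_array(scores)
    if not cells.equals(model.assignments.index):
        raise StateError("scores and model cover different cells")
    cut = X.mean(axis=0) + X.std(axis=0, ddof=0)
    lab = model.assignments.to_numpy()
    means, fracs, sizes = {}, {}, {}
    for c in model.centroids.index:
        members = X[lab == c]
        sizes[c] = members.shape[0]
        if members.shape[0] == 0:
            means[c] = np.full(len(srps), np.nan)
            fracs[c] = np.full(len(srps), np.nan)
        else:
            means[c] = members.mean(axis=0)
            fracs[c] = (members > cut[None, :]).mean(axis=0)
    mean_df = pd.DataFrame(means, index=srps).T
    frac_df = pd.DataFrame(fracs, index=srps).T
    mean_df.index.name = frac_df.index.name = "cluster"
    return ClusterSummary(
        mean_df, frac_df, pd.Series(sizes, name="size").rename_axis("cluster")
    )


@dataclass
class Dendrogram:
    """Ward/Euclidean agglomeration of cluster centroids."""

    linkage_matrix: np.ndarray     # scipy linkage format, k - 1 merges
    leaves: list[int]              # cluster ids in leaf order
    cluster_ids: list[int]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def centroid_hierarchy(model: StateModel) -> Dendrogram:
    """Ward linkage over centroids with Euclidean distances."""
    Z = linkage(model.centroids.to_numpy(), method="ward")
    ids = list(model.centroids.index)
    return Dendrogram(Z, [ids[i] for i in leaves_list(Z)], ids)


def assign_groups(
    dendrogram: Dendrogram,
    model: StateModel,
    n_groups: int = 5,
    weighted_activation: bool = False,
    override: dict[int, str] | None = None,
) -> pd.Series:
    """Cut the centroid dendrogram into phenotypic groups.

    Groups are the ``n_groups`` branches left after removing the
    (n_groups - 1) highest merges; labels I, II, ... are assigned in
    ascending order of the group's mean total pathway activation (sum of
    centroid entries, optionally weighted by cluster size), so Group I is
    the most basal.  ``override`` replaces the automatic cluster -> label
    map for any listed cluster.
    """
    k = len(dendrogram.cluster_ids)
    if n_groups > k:
        raise StateError(f"cannot cut {k} clusters into {n_groups} groups")
    flat = fcluster(dendrogram.linkage_matrix, t=n_groups, criterion="maxclust")
    raw = pd.Series(flat, index=dendrogram.cluster_ids, name="group")
    activation = model.centroids.sum(axis=1)
    if weighted_activation:
        w = model.cluster_sizes()
        group_act = (activation * w).groupby(raw).sum() / w.groupby(raw).sum()
    else:
        group_act = activation.groupby(raw).mean()
    order = group_act.sort_values(kind="stable").index
    label_map = {g: _roman(i) for i, g in enumerate(order)}
    labels = raw.map(label_map).rename("group")
    if override:
        for cluster, label in override.items():
            labels.loc[cluster] = label
    return labels


def occupancy(model: StateModel, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each treatment's cells in each cluster (rows sum to 1)."""
    df = pd.DataFrame(
        {
            "cluster": model.assignments,
            "chemical": cell_meta["chemical"],
            "conc": cell_meta["conc"],
        }
    )
    counts = (
        df.groupby(["chemical", "conc", "cluster"], sort=True)
        .size()
        .unstack("cluster", fill_value=0)
        .reindex(columns=model.centroids.index, fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def plot_dot_heatmap(summary: ClusterSummary, path: str | Path) -> None:
    """Dot-heatmap of clusters × pathways: colour = mean score, radius =
    fraction of cells above the global mean + 1 SD."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = summary.mean_score
    frac = summary.frac_high
    n_c, n_s = mean.shape
    fig, ax = plt.subplots(figsize=(1 + 0.5 * n_s, 1 + 0.3 * n_c))
    vmax = np.nanmax(np.abs(mean.to_numpy())) or 1.0
    for i, c in enumerate(mean.index):
        for j, s in enumerate(mean.columns):
            ax.scatter(
                j,
                i,
                s=20 + 280 * np.nan_to_num(frac.loc[c, s]),
                c=[mean.loc[c, s]],
                cmap="RdBu_r",
                vmin=-vmax,
                vmax=vmax,
                edgecolors="grey",
                linewidths=0.3,
            )
    ax.set_xticks(range(n_s), mean.columns, rotation=45)
    ax.set_yticks(range(n_c), [str(c) for c in mean.index])
    ax.set_xlabel("stress response pathway")
    ax.set_ylabel("cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
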