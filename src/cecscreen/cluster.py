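"""Two-way co-occurrence clustering of rank-transformed site maxima.

Site maxima span orders of magnitude across chemicals, so each chemical's
concentrations are first replaced by their ranks across sites (average
ranks for ties; all-nondetect zeros share the lowest average rank).  Both
axes — chemicals and sites — are then clustered agglomeratively on
Euclidean distances between rank vectors.  Rank transformation makes the
clustering invariant under any strictly monotone per-chemical rescaling of
the raw concentrations.

The agglomeration is written here rather than delegated so that ties in
the distance structure (common with rank data) are broken deterministically:
at every step the minimum-distance pair is merged, and among equal-distance
pairs the one whose (sorted) cluster leaf-label tuples compare
lexicographically smallest wins.  This makes dendrograms reproducible
across runs and platforms.  The merge table uses the same encoding as
scipy linkage matrices, so scipy's dendrogram/validation utilities apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .model import Dendrogram, SiteMaxMatrix

log = logging.getLogger(__name__)

LINKAGES = ("complete", "average", "single")

CHEMICALS = "chemicals"
SITES = "sites"


def rank_transform(site_max: SiteMaxMatrix) -> pd.DataFrame:
    """Within-chemical ranks of the site maxima (1..n_sites, average ties).

    Returns a sites × chemicals frame.  A chemical with identical values at
    every site keeps its (constant) average ranks and is retained with a
    warning — it carries no ordering information but keeps site vectors
    complete.
    """
    values = site_max.values
    ranks = values.apply(lambda col: rankdata(col.to_numpy(), method="average"))
    constant = [c for c in values.columns if values[c].nunique() == 1]
    if constant:
        log.warning("constant-valued chemical(s) retained in ranks: %s", constant)
    return ranks


def pairwise_euclidean(rank_matrix: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between rank vectors.

    ``axis="chemicals"`` compares columns (chemical co-occurrence profiles
    across sites); ``axis="sites"`` compares rows (site signatures across
    the chemical panel).
    """
    if axis == CHEMICALS:
        data = rank_matrix.to_numpy().T
        labels = list(rank_matrix.columns)
    elif axis == SITES:
        data = rank_matrix.to_numpy()
        labels = list(rank_matrix.index)
    else:
        raise ValueError(f"axis must be {CHEMICALS!r} or {SITES!r}")
    if np.isnan(data).any():
        raise ValueError("rank matrix contains missing entries")
    dist = squareform(pdist(data, metric="euclidean"))
    return pd.DataFrame(dist, index=labels, columns=labels)


def agglomerate(
    distance: pd.DataFrame, linkage: str = "complete", axis: str = CHEMICALS
) -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    Stored-matrix algorithm with Lance–Williams updates for complete,
    average (UPGMA), and single linkage.  Among minimum-distance pairs,
    the pair with the lexicographically smallest (sorted leaf-label tuple)
    cluster labels merges first.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    labels = [str(x) for x in distance.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two leaves to cluster")
    D = distance.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    np.fill_diagonal(D, np.inf)  # inactive entries masked with +inf
    node_id = {i: i for i in range(n)}  # slot -> dendrogram node id
    size = np.ones(n)
    key = {i: (labels[i],) for i in range(n)}  # sorted leaf tuple per slot
    merges = np.empty((n - 1, 4), dtype=float)

    for step in range(n - 1):
        dmin = D.min()
        ties = np.argwhere(D == dmin)
        a, b = min(
            ((int(i), int(j)) for i, j in ties if i < j),
            key=lambda p: tuple(sorted((key[p[0]], key[p[1]]))),
        )
        merges[step] = (
            min(node_id[a], node_id[b]),
            max(node_id[a], node_id[b]),
            dmin,
            size[a] + size[b],
        )
        da, db = D[a].copy(), D[b].copy()
        if linkage == "complete":
            row = np.maximum(da, db)
        elif linkage == "single":
            row = np.minimum(da, db)
        else:
            row = (size[a] * da + size[b] * db) / (size[a] + size[b])
        row[a] = row[b] = np.inf
        D[a, :] = D[:, a] = row
        D[b, :] = D[:, b] = np.inf
        node_id[a] = n + step
        size[a] += size[b]
        key[a] = tuple(sorted(key[a] + key[b]))
    return Dendrogram(leaf_labels=labels, merges=merges, axis=axis)


def leaf_order(dendrogram: Dendrogram) -> List[str]:
    """Display order from recursive traversal, tighter subcluster first.

    At each internal node the child with the smaller merge height (leaves
    count as height 0) is emitted first; ties fall back to the
    lexicographically smaller leaf-label tuple.
    """
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    key = {i: (dendrogram.leaf_labels[i],) for i in range(n)}
    children: Dict[int, Tuple[int, int]] = {}
    for i, (a, b, h, _s) in enumerate(dendrogram.merges):
        node = n + i
        a, b = int(a), int(b)
        children[node] = (a, b)
        height[node] = float(h)
        key[node] = tuple(sorted(key[a] + key[b]))

    order: List[str] = []

    def visit(node: int) -> None:
        if node < n:
            order.append(dendrogram.leaf_labels[node])
            return
        a, b = children[node]
        first, second = sorted((a, b), key=lambda c: (height[c], key[c]))
        visit(first)
        visit(second)

    visit(2 * n - 2)
    return order


def cut_clusters(dendrogram: Dendrogram, k: int) -> Dict[str, int]:
    """Partition the leaves into exactly k groups.

    Applies the first n − k merges and labels the resulting components
    0..k-1 in order of each component's first leaf.  Equivalent to cutting
    the tree just below the height of merge n − k + 1.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):
        a, b, _h, _s = dendrogram.merges[i]
        node = n + i
        parent[find(int(a))] = node
        parent[find(int(b))] = node
    roots: Dict[int, int] = {}
    labels: Dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in roots:
            roots[root] = len(roots)
        labels[dendrogram.leaf_labels[leaf]] = roots[root]
    return labels


def export_newick(dendrogram: Dendrogram, path=None) -> str:
    """Newick string with branch lengths = parent height − child height."""
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: Dict[int, Tuple[int, int]] = {}
    for i, (a, b, h, _s) in enumerate(dendrogram.merges):
        children[n + i] = (int(a), int(b))
        height[n + i] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height.get(node, 0.0)
        if node < n:
            return f"{_escape(dendrogram.leaf_labels[node])}:{length:g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{length:g}"

    root = 2 * n - 2
    a, b = children[root]
    h = height[root]
    text = f"({render(a, h)},{render(b, h)});"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def _escape(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TwoWayOrder:
    """Result of two-way clustering: trees, leaf orders, and rank matrix —
    everything needed to render an ordered co-occurrence heatmap."""

    chemical_dendrogram: Dendrogram
    site_dendrogram: Dendrogram
    chemical_order: List[str]
    site_order: List[str]
    rank_matrix: pd.DataFrame

    @property
    def ordered_ranks(self) -> pd.DataFrame:
        return self.rank_matrix.loc[self.site_order, self.chemical_order]


def two_way_order(
    site_max: SiteMaxMatrix, linkage: str = "complete"
) -> TwoWayOrder:
    """Cluster both axes of a (panel-filtered) site-max matrix."""
    ranks = rank_transform(site_max)
    chem_tree = agglomerate(
        pairwise_euclidean(ranks, CHEMICALS), linkage, axis=CHEMICALS
    )
    site_tree = agglomerate(
        pairwise_euclidean(ranks, SITES), linkage, axis=SITES
    )
    return TwoWayOrder(
        chemical_dendrogram=chem_tree,
        site_dendrogram=site_tree,
        chemical_order=leaf_order(chem_tree),
        site_order=leaf_order(site_tree),
        rank_matrix=ranks,
    )


def plot_heatmap(order: TwoWayOrder, path) -> None:
    """Render the ordered rank heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = order.ordered_ranks
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * data.shape[1]), max(6, 0.2 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="rank (lighter = lower)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
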