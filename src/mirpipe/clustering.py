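"""Agglomerative hierarchical clustering: Euclidean distance, Ward linkage.

Ward's criterion merges, at each step, the pair of clusters whose fusion
minimally increases the total within-cluster variance.  The agglomeration is
run with the Lance–Williams update

    d(k, i∪j)² = [(n_i+n_k) d(k,i)² + (n_j+n_k) d(k,j)² − n_k d(i,j)²] / (n_i+n_j+n_k)

on squared Euclidean distances, with merge heights reported on the distance
scale (the "Ward.D2" convention, matching criterion-faithful implementations).
A legacy variant applying the same update to unsquared distances is available
for parity with older software.  Ties are broken deterministically by the
smallest cluster-index pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ValidationError


def euclidean_distances(m: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Symmetric Euclidean distance matrix over rows or columns of ``m``."""
    X = np.asarray(m, dtype=float)
    if axis == "columns":
        X = X.T
    elif axis != "rows":
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("distance input contains non-finite values")
    return squareform(pdist(X, metric="euclidean"))


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` lists, per step, ``(id_a, id_b, height, size)`` in scipy's id
    convention: leaves are 0..n−1 and the cluster created at step ``s`` has id
    ``n + s``.  ``leaf_labels`` names the leaves in input order.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n−1) × 4 linkage matrix."""
        return np.array(
            [[a, b, h, s] for a, b, h, s in self.merges], dtype=float
        )

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + s: (a, b) for s, (a, b, _, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf ordering consistent with the merge tree."""
        n = self.n_leaves
        if n == 1:
            return list(self.leaf_labels)
        children = self._children()
        root = n + len(self.merges) - 1
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                a, b = children[node]
                stack.extend((b, a))  # a traversed first
        return [self.leaf_labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = self.n_leaves
        children = self._children()
        heights = {i: 0.0 for i in range(n)}
        for s, (_, _, h, _) in enumerate(self.merges):
            heights[n + s] = h

        def node_str(node: int, parent_h: float) -> str:
            bl = max(parent_h - heights[node], 0.0)
            if node < n:
                return f"{self.leaf_labels[node]}:{bl:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({node_str(a, h)},{node_str(b, h)}):{bl:.10g}"

        if n == 1:
            return f"{self.leaf_labels[0]}:0;"
        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({node_str(a, h)},{node_str(b, h)});"


def ward_linkage(
    d: np.ndarray,
    leaf_labels: list[str] | None = None,
    variant: str = "D2",
) -> Dendrogram:
    """Ward agglomeration of a Euclidean distance matrix.

    ``variant="D2"`` (default) runs Lance–Williams on squared distances and
    reports heights on the distance scale; ``variant="D"`` applies the same
    update to the distances as given (legacy behaviour of some environments).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ValidationError("clustering needs at least 2 items")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValidationError("distance matrix must be non-negative")
    if variant not in ("D2", "D"):
        raise ValidationError(f"unknown Ward variant '{variant}'")
    labels = list(leaf_labels) if leaf_labels is not None else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("leaf_labels length mismatch")

    C = d**2 if variant == "D2" else d.copy()
    np.fill_diagonal(C, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    ids = np.arange(n)
    merges: list[tuple[int, int, float, int]] = []

    work = C.copy()
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        np.fill_diagonal(masked, np.inf)
        # row-major argmin -> smallest (i, j) pair on ties; positions are in
        # cluster-creation order so this is the smallest cluster-index pair
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        cost = masked[i, j]
        height = float(np.sqrt(cost)) if variant == "D2" else float(cost)
        ni, nj = sizes[i], sizes[j]
        new_size = int(ni + nj)
        merges.append((int(ids[i]), int(ids[j]), height, new_size))
        # Lance-Williams Ward update against every other active cluster
        k_mask = active.copy()
        k_mask[[i, j]] = False
        nk = sizes[k_mask]
        work_new = (
            (ni + nk) * work[i, k_mask]
            + (nj + nk) * work[j, k_mask]
            - nk * cost
        ) / (ni + nj + nk)
        work[i, k_mask] = work_new
        work[k_mask, i] = work_new
        active[j] = False
        sizes[i] = new_size
        ids[i] = n + step
    return Dendrogram(merges=merges, leaf_labels=labels)


def leaf_order(dend: Dendrogram) -> list[str]:
    """Convenience wrapper over :meth:`Dendrogram.leaf_order`."""
    return dend.leaf_order()


class WardClustering(ClusterMixin, BaseEstimator):
    """Ward hierarchical clustering as a scikit-learn estimator.

    ``fit(X)`` clusters the rows of ``X``; fitted attributes are
    ``dendrogram_``, ``linkage_`` (scipy format) and, when ``n_clusters`` is
    set, flat ``labels_`` from cutting the tree.
    """

    def __init__(self, n_clusters: int | None = None, variant: str = "D2"):
        self.n_clusters = n_clusters
        self.variant = variant

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        d = euclidean_distances(X, axis="rows")
        self.dendrogram_ = ward_linkage(d, variant=self.variant)
        self.linkage_ = self.dendrogram_.to_linkage_matrix()
        if self.n_clusters is not None:
            from scipy.cluster.hierarchy import fcluster

            self.labels_ = fcluster(self.linkage_, self.n_clusters, criterion="maxclust") - 1
        else:
            self.labels_ = np.zeros(X.shape[0], dtype=int)
        return self
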