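"""Agglomerative UPGMA clustering of expression profiles.

Unweighted average linkage on Euclidean distances between per-gene
condition profiles, with fully deterministic behaviour: distance ties are
broken toward the pair containing the lowest original gene index, and the
leaf order is the recursive left-subtree-first traversal where the left
child is the subtree containing the smaller minimum leaf index.

The merge table uses the same layout as a scipy linkage matrix
(child_a, child_b, height, size), so scipy tooling (cophenet, dendrogram)
can consume it directly in cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["Dendrogram", "hierarchical_cluster"]


class MissingValueError(ValueError):
    """Raised on NaN input; impute or drop incomplete genes upstream."""


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree in linkage-matrix form plus leaf labels."""

    merges: np.ndarray  # (n-1, 4): child_a, child_b, height, size
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Leaf indices by recursive left-first traversal.

        The left child of every merge is the one whose subtree contains the
        smaller minimum leaf index.
        """
        n = self.n_leaves
        children = {n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(self.merges)}
        min_leaf: dict[int, int] = {i: i for i in range(n)}
        for node in sorted(children):
            a, b = children[node]
            min_leaf[node] = min(min_leaf[a], min_leaf[b])
        order: list[int] = []
        stack = [n + len(children) - 1] if children else [0]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
                continue
            a, b = children[node]
            left, right = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
            stack.append(right)
            stack.append(left)
        return order

    def to_dict(self) -> dict:
        """Nested JSON-serializable tree with merge heights."""
        n = self.n_leaves

        def build(node: int) -> dict:
            if node < n:
                return {"leaf": self.labels[node]}
            a, b, h, size = self.merges[node - n]
            ca, cb = build(int(a)), build(int(b))
            return {"height": float(h), "size": int(size), "children": [ca, cb]}

        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return build(root)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def hierarchical_cluster(profiles: np.ndarray, labels=None) -> Dendrogram:
    """UPGMA on Euclidean distances between row profiles.

    Inter-cluster distance is the unweighted mean of all pairwise member
    distances, maintained by the Lance–Williams average-linkage update
    d(a∪b, k) = (n_a·d(a,k) + n_b·d(b,k)) / (n_a + n_b).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if np.isnan(profiles).any():
        raise MissingValueError("profiles contain NaN; drop or impute incomplete genes upstream")
    n = profiles.shape[0]
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    else:
        labels = tuple(labels)
        if len(labels) != n:
            raise ValueError("labels length mismatch")

    dist = squareform(pdist(profiles, metric="euclidean"))
    np.fill_diagonal(dist, np.inf)
    active = list(range(n))            # current cluster ids, linkage numbering
    row_of = {cid: i for i, cid in enumerate(active)}  # cluster id -> matrix row
    sizes = {cid: 1 for cid in active}
    min_leaf = {cid: cid for cid in range(n)}
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        # locate the global minimum; ties -> pair with the lowest gene index
        rows = np.array([row_of[c] for c in active])
        sub = dist[np.ix_(rows, rows)]
        d = sub.min()
        tie_i, tie_j = np.nonzero(sub == d)
        best = None
        best_key = None
        for ia, ib in zip(tie_i, tie_j):
            if ia >= ib:
                continue
            ca_, cb_ = active[int(ia)], active[int(ib)]
            key = (min(min_leaf[ca_], min_leaf[cb_]), max(min_leaf[ca_], min_leaf[cb_]))
            if best_key is None or key < best_key:
                best_key = key
                best = (ca_, cb_)
        ca, cb = best
        new_id = n + step
        merges[step] = (min(ca, cb), max(ca, cb), d, sizes[ca] + sizes[cb])

        ra, rb = row_of[ca], row_of[cb]
        na, nb = sizes[ca], sizes[cb]
        for ck in active:
            if ck in (ca, cb):
                continue
            rk = row_of[ck]
            merged = (na * dist[ra, rk] + nb * dist[rb, rk]) / (na + nb)
            dist[ra, rk] = dist[rk, ra] = merged
        dist[rb, :] = np.inf
        dist[:, rb] = np.inf

        active.remove(ca)
        active.remove(cb)
        active.append(new_id)
        row_of[new_id] = ra
        sizes[new_id] = na + nb
        min_leaf[new_id] = min(min_leaf[ca], min_leaf[cb])

    return Dendrogram(merges=merges, labels=labels)
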