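"""Row normalization and agglomerative clustering of species profiles.

The assay matrix is normalized per assay (row) across species to remove
magnitudinal differences between assays, then species (columns) are
clustered by Manhattan (L1) distance with complete linkage, matching the
heatmap's column dendrogram. Complete linkage is implemented directly via
the Lance-Williams max-update so the tie-breaking rule is an explicit
contract: among equidistant pairs, the pair with the lexicographically
smallest (cluster-id, cluster-id) merges first, where leaves are numbered
0..n-1 in column order and each new cluster takes the next id.

Merge heights under complete linkage on a metric are non-decreasing, so
the resulting dendrogram is ultrametric and a k-cluster partition is
obtained by undoing the last k-1 merges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .reporter import AssayMatrix

__all__ = [
    "Dendrogram",
    "row_normalize",
    "species_distance",
    "complete_linkage",
    "cut_partition",
    "is_clade",
    "to_newick",
]


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over named leaves.

    ``merges`` has one row per merge: (child_a, child_b, height), where ids
    0..n-1 are leaves in ``leaves`` order and merge i creates id n+i.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(h < 0 for h in heights):
            raise ValueError("merge heights must be >= 0")
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing (ultrametric)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_leafsets(self) -> list[frozenset]:
        """Leaf-name descendant sets for every node, indexed by node id."""
        sets: list[frozenset] = [frozenset([name]) for name in self.leaves]
        for a, b, _ in self.merges:
            sets.append(sets[a] | sets[b])
        return sets


def row_normalize(matrix: AssayMatrix, method: str = "zscore") -> AssayMatrix:
    """Normalize each assay row across species.

    ``zscore``: zero mean, unit sample SD (ddof=1); ``minmax``: map to
    [0, 1]; ``none``: identity. Constant rows map to all-zeros under
    either transform (guard against 0/0). Idempotent for zscore.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("row normalization needs >=2 species per row")
    if method == "none":
        return AssayMatrix(values.copy(), matrix.annotations)
    if method == "zscore":
        centered = values.sub(values.mean(axis=1), axis=0)
        sd = values.std(axis=1, ddof=1)
        out = centered.div(sd.where(sd > 0, np.inf), axis=0)
    elif method == "minmax":
        lo = values.min(axis=1)
        span = values.max(axis=1) - lo
        out = values.sub(lo, axis=0).div(span.where(span > 0, np.inf), axis=0)
    else:
        raise ValueError(f"unknown normalization {method!r}; use zscore|minmax|none")
    return AssayMatrix(out, matrix.annotations)


def species_distance(matrix: AssayMatrix) -> pd.DataFrame:
    """Pairwise Manhattan distance between species columns."""
    cols = matrix.values.to_numpy().T
    dist = cdist(cols, cols, metric="cityblock")
    return pd.DataFrame(dist, index=matrix.species, columns=matrix.species)


def manhattan_condensed(values: np.ndarray) -> np.ndarray:
    """Square L1 distance matrix between columns of a 2-D array (fast path)."""
    cols = values.T
    return np.abs(cols[:, None, :] - cols[None, :, :]).sum(axis=2)


def complete_linkage(dist, leaves: tuple[str, ...] | None = None) -> Dendrogram:
    """Agglomerate with inter-cluster distance = max pairwise member distance.

    Accepts a labelled DataFrame (from :func:`species_distance`) or a
    square ndarray with explicit ``leaves``. Deterministic under the
    declared smallest-(id, id) tie rule.
    """
    if isinstance(dist, pd.DataFrame):
        leaves = tuple(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if leaves is None:
            raise ValueError("ndarray input requires leaf names")
        leaves = tuple(leaves)
    n = len(leaves)
    if n < 2:
        raise ValueError("clustering needs >=2 leaves")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match leaves")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    # active clusters: id -> row index into the working distance matrix
    work = d.copy()
    ids = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        m = len(ids)
        best = None  # (height, id_a, id_b, pos_a, pos_b)
        for i in range(m):
            for j in range(i + 1, m):
                key = (work[i, j], ids[i], ids[j])
                if best is None or key < best[:3]:
                    best = (work[i, j], ids[i], ids[j], i, j)
        h, ida, idb, i, j = best
        merges.append((ida, idb, float(h)))
        # Lance-Williams complete-linkage update: d(new, k) = max(d(i,k), d(j,k))
        new_row = np.maximum(work[i], work[j])
        keep = [p for p in range(m) if p not in (i, j)]
        work = work[np.ix_(keep, keep)]
        new_to_keep = new_row[keep]
        work = np.pad(work, ((0, 1), (0, 1)))
        work[-1, :-1] = new_to_keep
        work[:-1, -1] = new_to_keep
        ids = [ids[p] for p in keep] + [next_id]
        next_id += 1
    return Dendrogram(tuple(merges), leaves)


def cut_partition(tree: Dendrogram, k: int) -> list[frozenset]:
    """The k clusters obtained by undoing the k-1 highest (last) merges.

    Returned as leaf-name sets sorted by their smallest member for
    determinism.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _) in enumerate(tree.merges[: n - k]):
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node
    groups: dict[int, set] = {}
    for leaf, name in enumerate(tree.leaves):
        groups.setdefault(find(leaf), set()).add(name)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def is_clade(tree: Dendrogram, leafset) -> bool:
    """True iff some node's descendant leaf set equals ``leafset`` exactly."""
    target = frozenset(leafset)
    unknown = target - set(tree.leaves)
    if unknown:
        raise ValueError(f"unknown leaf names {sorted(unknown)}")
    return target in set(tree.node_leafsets())


def to_newick(tree: Dendrogram) -> str:
    """Ultrametric Newick serialization.

    Each node sits at elevation height/2 (leaves at 0), so a branch length
    is (parent merge height - child merge height)/2 and every root-to-leaf
    path has length max-height/2. Topology and clade structure survive a
    parse/serialize round trip.
    """
    n = tree.n_leaves
    labels = [name for name in tree.leaves]
    elevation = [0.0] * n
    leafsets = tree.node_leafsets()
    for a, b, h in tree.merges:
        # children ordered by their smallest leaf name, for a canonical string
        if min(leafsets[b]) < min(leafsets[a]):
            a, b = b, a
        la = f"{labels[a]}:{h / 2 - elevation[a]:g}"
        lb = f"{labels[b]}:{h / 2 - elevation[b]:g}"
        labels.append(f"({la},{lb})")
        elevation.append(h / 2)
    return labels[-1] + ";"
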