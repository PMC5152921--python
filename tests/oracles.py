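"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the linkage oracle
recomputes inter-cluster distances as explicit maxima over all member
pairs from the original matrix at every step (O(n^3) agglomeration), and
the bootstrap oracle enumerates every ordered resample-with-replacement.
"""

from itertools import product

import numpy as np


def naive_complete_linkage(dist: np.ndarray):
    """O(n^3) agglomeration: clusters as leaf-index sets, max-pair distance.

    Ties broken by the smallest (cluster-id, cluster-id) pair, leaves
    numbered 0..n-1 and each merge taking the next id. Returns a list of
    (leafset_a, leafset_b, height) with leafsets as frozensets of leaf
    indices.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for ida in sorted(clusters):
            for idb in sorted(clusters):
                if ida >= idb:
                    continue
                d = max(dist[x, y] for x in clusters[ida] for y in clusters[idb])
                key = (d, ida, idb)
                if best is None or key < best:
                    best = key
        d, ida, idb = best
        merges.append((clusters[ida], clusters[idb], d))
        clusters[next_id] = clusters.pop(ida) | clusters.pop(idb)
        next_id += 1
    return merges


def enumerate_recapitulation(values: np.ndarray, leaves, score_fn):
    """Exact plain-bootstrap rate: average score over all n^n ordered resamples."""
    n = values.shape[0]
    hits = 0
    total = 0
    for rows in product(range(n), repeat=n):
        hits += score_fn(values[list(rows)], leaves)
        total += 1
    return hits / total
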