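"""Effective counting of entangled loops by greedy clustering.

Within one protein, many entangled loops are near-duplicates of the same
topological configuration (e.g. the loops closed by (i1, i2) and by
(i1 + 1, i2) wound around the same thread). To avoid over-counting, loops
are clustered with the distance

    d_AB = sqrt( (i1A−i1B)² + (i2A−i2B)² + (j1A−j1B)² + (j2A−j2B)²
                 + w_g (gA − gB)² )

and every loop in a cluster of N_C members enters downstream statistics with
weight 1/N_C, so each cluster contributes one effective count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .gaussian import LoopRecord

#: Distance threshold defining cluster neighborhoods (index units).
D_STAR = 20.0
#: Weight converting squared score differences to squared index units.
W_G = 1.0e4


def loop_distance(a: LoopRecord, b: LoopRecord, w_g: float = W_G) -> float:
    """Distance between two entangled loops (Euclidean over the four
    subchain indices plus a ``w_g``-weighted squared score difference)."""
    return float(
        np.sqrt(
            (a.i1 - b.i1) ** 2
            + (a.i2 - b.i2) ** 2
            + (a.j1 - b.j1) ** 2
            + (a.j2 - b.j2) ** 2
            + w_g * (a.g - b.g) ** 2
        )
    )


@dataclass
class ClusterAssignment:
    """Cluster ids, sizes and per-loop weights for one protein's loops."""

    cluster_id: list[int]
    cluster_size: list[int]  # indexed by cluster id
    weights: list[float]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_size)


def cluster_loops(
    loops: list[LoopRecord],
    d_star: float = D_STAR,
    w_g: float = W_G,
    assign_weights: bool = True,
) -> ClusterAssignment:
    """Greedy neighbor clustering of one protein's entangled loops.

    Repeatedly select the loop with the largest number of neighbors within
    ``d_star`` (ties broken by lowest (i1, i2, j1, j2)), form a cluster from
    it and its neighbors, remove them, and iterate until no loops remain.
    Each member's weight is set to 1/N_C when ``assign_weights`` is true.
    """
    n = len(loops)
    if n == 0:
        return ClusterAssignment(cluster_id=[], cluster_size=[], weights=[])
    feats = np.array(
        [[r.i1, r.i2, r.j1, r.j2, np.sqrt(w_g) * r.g] for r in loops]
    )
    close = squareform(pdist(feats)) < d_star if n > 1 else np.ones((1, 1), bool)
    np.fill_diagonal(close, True)  # a loop is its own neighbor

    order = sorted(range(n), key=lambda k: (loops[k].i1, loops[k].i2,
                                            loops[k].j1, loops[k].j2))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    cluster_id = [-1] * n
    sizes: list[int] = []
    alive = np.ones(n, dtype=bool)
    while alive.any():
        idxs = np.flatnonzero(alive)
        counts = close[np.ix_(idxs, idxs)].sum(axis=1)
        best_count = counts.max()
        tied = idxs[counts == best_count]
        top = tied[np.argmin(rank[tied])]
        members = idxs[close[top, idxs]]
        cid = len(sizes)
        for j in members:
            cluster_id[int(j)] = cid
        alive[members] = False
        sizes.append(len(members))
    weights = [1.0 / sizes[cluster_id[k]] for k in range(n)]
    if assign_weights:
        for r, w in zip(loops, weights):
            r.weight = w
    return ClusterAssignment(cluster_id=cluster_id, cluster_size=sizes,
                             weights=weights)


def cluster_by_protein(
    loops: list[LoopRecord],
    d_star: float = D_STAR,
    w_g: float = W_G,
) -> dict[str, ClusterAssignment]:
    """Cluster entangled loops independently within each protein and write
    the 1/N_C weights back onto the records. Non-entangled or thread-less
    loops are left untouched (weight 1)."""
    by_protein: dict[str, list[LoopRecord]] = {}
    for r in loops:
        if r.entangled:
            by_protein.setdefault(r.protein_id, []).append(r)
    return {
        pid: cluster_loops(group, d_star=d_star, w_g=w_g)
        for pid, group in by_protein.items()
    }
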