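"""Neighbor-count (Daura-style) conformational clustering by pairwise Cα-RMSD.

The greedy protocol: among the structures not yet assigned, pick the one
with the largest number of neighbors within the RMSD cutoff (ties: lowest
index); that structure is the cluster representative and forms a cluster
together with its neighbors; remove them all and repeat until every
structure is assigned.  Cluster sizes are non-increasing by construction.

Conventions (the protocol leaves them open): a distance exactly equal to
the cutoff counts as a neighbor; a structure is not its own neighbor, so a
cluster of a representative with ``k`` neighbors has size ``k + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Structure
from .orderparams import OrderParamSpec, ca_rmsd


@dataclass
class ClusterResult:
    """Partition of the input structures into clusters.

    ``clusters[i]`` lists member indices of cluster ``i`` (largest first);
    ``centroids[i]`` is the representative's index and belongs to its
    cluster; ``cutoff`` is the neighbor cutoff in Å.
    """

    clusters: list[list[int]]
    centroids: list[int]
    cutoff: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def pairwise_rmsd_matrix(structures: Sequence[Structure], selection=None) -> np.ndarray:
    """Symmetric matrix of pairwise Cα-RMSDs (each pair optimally
    superposed on ``selection``; default: all residues of the first
    structure)."""
    if not structures:
        raise ValueError("need at least one structure")
    if selection is None:
        selection = tuple(int(r) for r in structures[0].residue_numbers)
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        spec = OrderParamSpec("rmsd", selection, reference=structures[i])
        for j in range(i + 1, n):
            d = ca_rmsd(structures[j], spec)
            mat[i, j] = mat[j, i] = d
    return mat


def daura_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbor-count clustering of a pairwise distance matrix."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mat = np.asarray(matrix, dtype=float)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("matrix must be square")

    remaining = np.ones(n, dtype=bool)
    neighbor = (mat <= cutoff) & ~np.eye(n, dtype=bool)
    clusters: list[list[int]] = []
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[rep] & remaining).tolist()
        cluster = sorted([rep] + members)
        clusters.append(cluster)
        centroids.append(rep)
        remaining[cluster] = False
    return ClusterResult(clusters=clusters, centroids=centroids, cutoff=float(cutoff))


def write_cluster_report(result: ClusterResult, path, min_fraction: float = 0.0) -> None:
    """Tab-separated cluster report (id, size, centroid, members).

    ``min_fraction`` drops families below that fraction of all snapshots
    (reporting filter; default keeps everything).
    """
    total = sum(result.sizes)
    with open(path, "w") as fh:
        fh.write("cluster\tsize\tfraction\tcentroid\tmembers\n")
        for k, (members, rep) in enumerate(zip(result.clusters, result.centroids)):
            frac = len(members) / total
            if frac < min_fraction:
                continue
            member_str = ",".join(str(m) for m in members)
            fh.write(f"{k}\t{len(members)}\t{frac:.6f}\t{rep}\t{member_str}\n")
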