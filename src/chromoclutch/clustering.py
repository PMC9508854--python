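"""Representative-structure extraction by single-linkage RMSD clustering.

Configurations are compared by optimal-superposition RMSD over nucleosome
centers (centroid removal + Kabsch rotation); ensembles are partitioned by
single-linkage clustering at a distance cutoff, and each cluster is
summarized by its medoid ("central configuration").  Note that
superposition RMSD violates the triangle inequality in general, so the
partition is defined as the connected components of the dist < cutoff
graph — exactly the single-linkage dendrogram cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.transform import Rotation

from .colvars import ee_per_nuc
from .structures import ChromatinConfig

__all__ = [
    "rmsd",
    "single_linkage",
    "representative",
    "select_representatives",
    "ClusterResult",
    "pairwise_rmsd",
]


def rmsd(a: ChromatinConfig, b: ChromatinConfig) -> float:
    """Optimal-superposition RMSD over nucleosome centers, nm.

    Centroids are removed and the optimal (proper) rotation applied before
    averaging squared deviations; rigid-motion copies score 0.
    """
    pa = a.all_centers()
    pb = b.all_centers()
    if pa.shape != pb.shape:
        raise ValueError("configurations differ in chain count or lengths")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


def pairwise_rmsd(ensemble: Sequence[ChromatinConfig]) -> np.ndarray:
    """Symmetric RMSD matrix of an ensemble."""
    n = len(ensemble)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd(ensemble[i], ensemble[j])
    return D


@dataclass
class ClusterResult:
    """Partition of an ensemble with per-cluster medoids.

    Cluster ids are 0-based and ordered by decreasing size (ties broken by
    the lowest member index).
    """

    labels: np.ndarray
    sizes: np.ndarray
    representative_index: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def single_linkage(dist_matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Single-linkage partition at ``cutoff``: connected components of the
    dist < cutoff graph (strict inequality)."""
    D = np.asarray(dist_matrix, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist_matrix must be square")
    n = D.shape[0]
    adj = csr_matrix((D < cutoff) & ~np.eye(n, dtype=bool))
    _, comp = connected_components(adj, directed=False)
    # relabel by decreasing size, ties by lowest member index
    ids, counts = np.unique(comp, return_counts=True)
    first = np.array([np.argmax(comp == cid) for cid in ids])
    order = sorted(range(len(ids)), key=lambda k: (-counts[k], first[k]))
    relabel = {ids[k]: rank for rank, k in enumerate(order)}
    labels = np.array([relabel[c] for c in comp])
    sizes = np.array([counts[k] for k in order])
    reps = np.array([_medoid_index(D, np.flatnonzero(labels == cid))
                     for cid in range(len(ids))])
    return ClusterResult(labels=labels, sizes=sizes, representative_index=reps)


def _medoid_index(D: np.ndarray, members: np.ndarray) -> int:
    """Member minimizing summed distance to the others; ties -> lowest index."""
    sums = D[np.ix_(members, members)].sum(axis=1)
    return int(members[int(np.argmin(sums))])  # argmin takes the first tie


def representative(
    ensemble: Sequence[ChromatinConfig],
    result: ClusterResult,
    cluster_id: int,
    dist_matrix: np.ndarray | None = None,
) -> ChromatinConfig:
    """Medoid configuration of one cluster."""
    if not 0 <= cluster_id < result.n_clusters:
        raise ValueError(f"no cluster {cluster_id}")
    if dist_matrix is None:
        return ensemble[int(result.representative_index[cluster_id])]
    members = np.flatnonzero(result.labels == cluster_id)
    return ensemble[_medoid_index(np.asarray(dist_matrix), members)]


def select_representatives(
    ensemble: Sequence[ChromatinConfig],
    target_ee: float,
    tolerance: float,
    cutoff: float = 3.0,
    n_structures: int = 1,
) -> list[ChromatinConfig]:
    """Central configurations near a target extension.

    Filters the ensemble to configurations whose end-to-end distance per
    nucleosome lies within ``tolerance`` of ``target_ee``, clusters the
    remainder by single-linkage RMSD at ``cutoff``, and returns the medoids
    of the most populated clusters (largest first).
    """
    keep = [cfg for cfg in ensemble
            if abs(ee_per_nuc(cfg) - target_ee) <= tolerance]
    if not keep:
        warnings.warn("no configurations within tolerance of the target "
                      "extension", stacklevel=2)
        return []
    D = pairwise_rmsd(keep)
    result = single_linkage(D, cutoff)
    out = []
    for cid in range(min(n_structures, result.n_clusters)):
        out.append(keep[int(result.representative_index[cid])])
    return out
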