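"""ε-threshold agglomerative clustering of trajectory frames.

Frames are compared by mask RMSD with *per-pair* optimal superposition (no
shared pre-alignment), merged by average linkage, and the hierarchy is cut
where the smallest inter-cluster average distance exceeds ε — the semantics
behind "RMSD threshold" clustering of MD trajectories.  Average linkage is
monotone, so cutting the scipy dendrogram at ε is exactly equivalent to
stopping the merge loop at ε.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, GeometryError
from .io import AtomMask, Topology, Trajectory
from .geometry import _resolve_mask, kabsch

__all__ = [
    "ClusterSet",
    "pairwise_rmsd_matrix",
    "cluster",
    "representative",
    "cluster_count_flexibility",
]


@dataclass
class ClusterSet:
    """Flat clustering of (possibly strided) frames.

    Clusters are numbered 1..k by descending population; ties break toward
    the cluster containing the lower frame index.  ``frame_indices`` maps
    positions in ``labels`` back to original frame numbers when a stride
    was applied.
    """

    labels: np.ndarray  # cluster id per clustered frame
    frame_indices: np.ndarray  # original frame index per clustered frame
    populations: dict[int, float]  # cluster id -> % of clustered frames
    representatives: dict[int, int]  # cluster id -> original frame index
    epsilon: float
    mask: str

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cid: int) -> np.ndarray:
        return self.frame_indices[self.labels == cid]

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "mask": self.mask,
            "n_clusters": self.n_clusters,
            "populations": {str(k): v for k, v in self.populations.items()},
            "representatives": {str(k): int(v) for k, v in self.representatives.items()},
            "labels": self.labels.tolist(),
            "frame_indices": self.frame_indices.tolist(),
        }


def pairwise_rmsd_matrix(
    traj: Trajectory,
    mask: np.ndarray | AtomMask | str,
    topology: Topology | None = None,
    frame_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Square matrix of pairwise optimal-superposition RMSDs on the mask."""
    idx = _resolve_mask(mask, topology)
    if idx.size < 3:
        raise GeometryError("clustering mask needs >= 3 atoms")
    frames = np.arange(traj.n_frames) if frame_indices is None else np.asarray(frame_indices)
    sel = traj.coordinates[frames][:, idx, :]
    n = sel.shape[0]
    centered = sel - sel.mean(axis=1, keepdims=True)
    norms = (centered**2).sum(axis=(1, 2))
    m = idx.size
    dm = np.zeros((n, n))
    for a in range(n):
        # batched 3x3 cross-covariances of frame a against all later frames
        C = np.einsum("ik,bil->bkl", centered[a], centered[a + 1:])
        S = np.linalg.svd(C, compute_uv=False)
        det = np.linalg.det(C)
        traces = S[:, 0] + S[:, 1] + np.where(det >= 0, S[:, 2], -S[:, 2])
        msd = (norms[a] + norms[a + 1:] - 2.0 * traces) / m
        dm[a, a + 1:] = np.sqrt(np.maximum(msd, 0.0))
    return dm + dm.T


def cluster(
    traj: Trajectory,
    mask: np.ndarray | AtomMask | str,
    epsilon: float,
    stride: int = 1,
    topology: Topology | None = None,
) -> ClusterSet:
    """Average-linkage agglomerative clustering with an ε stopping rule."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    frames = np.arange(0, traj.n_frames, stride)
    if frames.size < 2:
        raise DegenerateInputError("need >= 2 frames after stride")
    dm = pairwise_rmsd_matrix(traj, mask, topology, frames)
    Z = linkage(squareform(dm, checks=False), method="average")
    raw = fcluster(Z, t=epsilon, criterion="distance")
    labels, populations, representatives = _order_and_represent(raw, frames, dm)
    mask_str = mask.expression if isinstance(mask, AtomMask) else (
        mask if isinstance(mask, str) else f"indices[{np.asarray(mask).size}]"
    )
    return ClusterSet(
        labels=labels,
        frame_indices=frames,
        populations=populations,
        representatives=representatives,
        epsilon=float(epsilon),
        mask=mask_str,
    )


def _order_and_represent(raw, frames, dm):
    ids = np.unique(raw)
    stats = []
    for cid in ids:
        members = np.where(raw == cid)[0]
        stats.append((members.size, -int(members.min()), cid, members))
    # descending population; ties toward the cluster holding the lowest frame
    stats.sort(key=lambda s: (-s[0], -s[1]))
    labels = np.empty_like(raw)
    populations: dict[int, float] = {}
    representatives: dict[int, int] = {}
    total = raw.size
    for new_id, (size, _neg, _cid, members) in enumerate(stats, start=1):
        labels[members] = new_id
        populations[new_id] = 100.0 * size / total
        sub = dm[np.ix_(members, members)]
        mean_d = sub.mean(axis=1)  # includes the zero self-distance for all equally
        best = members[int(np.argmin(mean_d))]  # argmin takes the lowest index on ties
        representatives[new_id] = int(frames[best])
    return labels, populations, representatives


def representative(
    traj: Trajectory,
    members: np.ndarray,
    mask: np.ndarray | AtomMask | str,
    topology: Topology | None = None,
) -> int:
    """Frame minimizing the mean RMSD to all other members (tie → lowest)."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("members must be nonempty")
    if members.size == 1:
        return int(members[0])
    dm = pairwise_rmsd_matrix(traj, mask, topology, members)
    mean_d = dm.sum(axis=1) / (members.size - 1)
    return int(members[int(np.argmin(mean_d))])


def cluster_count_flexibility(cs: ClusterSet) -> tuple[int, float]:
    """(n_clusters, population entropy in nats) — larger means floppier.

    The Shannon entropy of the population distribution complements the raw
    cluster count: at equal evenness more clusters give a larger value, and
    a single cluster scores exactly zero.
    """
    p = np.array(list(cs.populations.values())) / 100.0
    p = p[p > 0]
    entropy = float(-(p * np.log(p)).sum())
    return cs.n_clusters, entropy
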