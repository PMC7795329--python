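"""Upper-body skeleton graph, spatial-configuration partitioning, bones.

The body is modelled as an undirected tree over V joints whose edges are
the natural bone connections.  Graph convolutions over the skeleton use
the spatial-configuration partitioning strategy: each node's 1-hop
neighbourhood (including itself) is split into three subsets by graph
distance to a designated body-centre joint (the spine base) —

* **root**: the node itself,
* **centripetal**: neighbours closer to the centre than the node,
* **centrifugal**: neighbours farther from the centre.

Each subset gets its own adjacency matrix ``A_k`` and its own weights in
the network, so information flowing toward and away from the body centre
is treated differently.

Bone features are the second-order representation: for every non-centre
joint ``j`` with parent ``p`` on the path toward the centre, the bone
vector is ``v_j - v_p`` (source = joint nearer the centre, target =
joint farther away); the centre joint carries a zero vector so both
streams share the ``T×V×3`` tensor shape.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SkeletonGraph",
    "PartitionedAdjacency",
    "SkeletonSequence",
    "BoneSequence",
    "UPPER_BODY_JOINTS",
    "UPPER_BODY_EDGES",
    "build_upper_body_graph",
    "spatial_partition",
    "joints_to_bones",
    "bones_to_joints",
]

# Default 10-joint upper-body roster.  Pose-estimation keypoint sets vary;
# this roster keeps one pelvis/spine-base point as the body centre even
# though the rest of the lower body is dropped.
UPPER_BODY_JOINTS: tuple[str, ...] = (
    "spine_base",      # 0, body centre
    "spine_chest",     # 1
    "neck",            # 2
    "head",            # 3
    "left_shoulder",   # 4
    "right_shoulder",  # 5
    "left_elbow",      # 6
    "right_elbow",     # 7
    "left_wrist",      # 8
    "right_wrist",     # 9
)

UPPER_BODY_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1),  # spine_base - spine_chest
    (1, 2),  # spine_chest - neck
    (2, 3),  # neck - head
    (2, 4),  # neck - left_shoulder
    (2, 5),  # neck - right_shoulder
    (4, 6),  # left_shoulder - left_elbow
    (5, 7),  # right_shoulder - right_elbow
    (6, 8),  # left_elbow - left_wrist
    (7, 9),  # right_elbow - right_wrist
)


@dataclass(frozen=True)
class SkeletonGraph:
    """An undirected joint graph with a designated body-centre joint."""

    num_joints: int
    edges: tuple[tuple[int, int], ...]
    center_joint: int = 0
    joint_names: tuple[str, ...] | None = None

    def __post_init__(self):
        edges = tuple(tuple(sorted(e)) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        v = self.num_joints
        for i, j in edges:
            if not (0 <= i < v and 0 <= j < v):
                raise ValueError(f"edge ({i}, {j}) out of range for V={v}")
            if i == j:
                raise ValueError(f"self-loop at joint {i}")
        if not 0 <= self.center_joint < v:
            raise ValueError(f"center_joint {self.center_joint} out of range")
        if self.joint_names is not None and len(self.joint_names) != v:
            raise ValueError("joint_names length must equal num_joints")

    def adjacency(self) -> np.ndarray:
        """Binary V×V adjacency matrix (no self-loops)."""
        a = np.zeros((self.num_joints, self.num_joints))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def hop_distance_to_center(self) -> np.ndarray:
        """Graph distance of every joint to the centre; -1 if unreachable."""
        dist = np.full(self.num_joints, -1, dtype=int)
        dist[self.center_joint] = 0
        adj = self.adjacency()
        queue = deque([self.center_joint])
        while queue:
            i = queue.popleft()
            for j in np.flatnonzero(adj[i]):
                if dist[j] < 0:
                    dist[j] = dist[i] + 1
                    queue.append(int(j))
        return dist

    def is_connected(self) -> bool:
        return bool((self.hop_distance_to_center() >= 0).all())

    def parents_toward_center(self) -> np.ndarray:
        """Parent of each joint on the unique tree path to the centre.

        The centre joint's parent is itself.  Requires a connected tree.
        """
        dist = self.hop_distance_to_center()
        if (dist < 0).any():
            missing = np.flatnonzero(dist < 0).tolist()
            raise ValueError(f"graph is disconnected; unreachable joints: {missing}")
        adj = self.adjacency()
        parent = np.full(self.num_joints, -1, dtype=int)
        parent[self.center_joint] = self.center_joint
        for j in range(self.num_joints):
            if j == self.center_joint:
                continue
            closer = [int(i) for i in np.flatnonzero(adj[j]) if dist[i] == dist[j] - 1]
            if len(closer) != 1:
                raise ValueError(f"joint {j} lacks a unique parent (graph is not a tree)")
            parent[j] = closer[0]
        return parent


@dataclass(frozen=True)
class PartitionedAdjacency:
    """K=3 adjacency subsets (root, centripetal, centrifugal)."""

    subsets: np.ndarray  # shape (3, V, V)
    normalized: bool

    @property
    def num_subsets(self) -> int:
        return self.subsets.shape[0]

    @property
    def num_joints(self) -> int:
        return self.subsets.shape[1]


@dataclass
class SkeletonSequence:
    """One labelled sample: a T×V×3 trajectory of 3D joint positions."""

    coords: np.ndarray
    label: int
    sample_id: str = ""
    frame_rate: float = 30.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be T×V×3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def num_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def num_joints(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "SkeletonSequence":
        return replace(self, coords=coords)


@dataclass
class BoneSequence(SkeletonSequence):
    """Second-order (bone-vector) form of a skeleton sequence."""


def build_upper_body_graph() -> SkeletonGraph:
    """The default 10-joint upper-body tree with the spine base as centre."""
    return SkeletonGraph(num_joints=10, edges=UPPER_BODY_EDGES, center_joint=0,
                         joint_names=UPPER_BODY_JOINTS)


def spatial_partition(graph: SkeletonGraph, normalize: bool = True,
                      eps: float = 1e-6) -> PartitionedAdjacency:
    """Split A+I into root / centripetal / centrifugal subsets.

    For each node ``i`` and each neighbour ``j`` (including ``j = i``):
    ``j = i`` goes to the root subset; ``j`` strictly closer to the body
    centre than ``i`` to the centripetal subset; strictly farther to the
    centrifugal subset.  Neighbours at equal distance (impossible on a
    tree, possible on general graphs) go to the centripetal subset —
    a deterministic tie-break.

    With ``normalize=True`` each subset is symmetrically degree
    normalized, ``D_k^{-1/2} A_k D_k^{-1/2}``, where empty rows get an
    ``eps`` pseudo-degree to avoid division by zero.
    """
    dist = graph.hop_distance_to_center()
    if (dist < 0).any():
        missing = np.flatnonzero(dist < 0).tolist()
        raise ValueError(f"graph is disconnected; unreachable joints: {missing}")
    v = graph.num_joints
    adj = graph.adjacency() + np.eye(v)
    subsets = np.zeros((3, v, v))
    for i in range(v):
        for j in range(v):
            if adj[i, j] == 0:
                continue
            if i == j:
                subsets[0, i, j] = 1.0
            elif dist[j] <= dist[i]:
                subsets[1, i, j] = 1.0   # centripetal (ties break here)
            else:
                subsets[2, i, j] = 1.0   # centrifugal
    if normalize:
        normed = np.empty_like(subsets)
        for k in range(3):
            deg = subsets[k].sum(axis=1)
            d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, eps))
            normed[k] = d_inv_sqrt[:, None] * subsets[k] * d_inv_sqrt[None, :]
            normed[k][deg == 0] = 0.0
        subsets = normed
    return PartitionedAdjacency(subsets=subsets, normalized=normalize)


def joints_to_bones(seq: SkeletonSequence, graph: SkeletonGraph) -> BoneSequence:
    """Derive bone vectors ``v_child - v_parent`` from joint positions.

    The parent is the adjacent joint nearer the body centre (the bone's
    source node); the centre joint itself gets a zero vector so joint and
    bone tensors share shape.
    """
    if seq.num_joints != graph.num_joints:
        raise ValueError(
            f"sequence has {seq.num_joints} joints but graph has {graph.num_joints}"
        )
    parent = graph.parents_toward_center()
    bones = seq.coords - seq.coords[:, parent, :]
    bones[:, graph.center_joint, :] = 0.0
    return BoneSequence(coords=bones, label=seq.label, sample_id=seq.sample_id,
                        frame_rate=seq.frame_rate)


def bones_to_joints(bones: BoneSequence, graph: SkeletonGraph,
                    center_trajectory: np.ndarray | None = None) -> SkeletonSequence:
    """Invert :func:`joints_to_bones` given the centre-joint trajectory."""
    parent = graph.parents_toward_center()
    t, v, _ = bones.coords.shape
    coords = np.zeros((t, v, 3))
    c = graph.center_joint
    coords[:, c, :] = 0.0 if center_trajectory is None else center_trajectory
    # accumulate outward in order of increasing distance to centre
    order = np.argsort(graph.hop_distance_to_center())
    for j in order:
        if j == c:
            continue
        coords[:, j, :] = coords[:, parent[j], :] + bones.coords[:, j, :]
    return SkeletonSequence(coords=coords, label=bones.label,
                            sample_id=bones.sample_id, frame_rate=bones.frame_rate)
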