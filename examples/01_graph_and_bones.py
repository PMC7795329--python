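"""Build the upper-body skeleton graph, partition it, derive bone features.

The 10-joint tree keeps the spine base as body centre; its neighbourhood
partition (root / centripetal / centrifugal) is what gives each
direction of information flow its own weights in the graph convolution.
Bone features are the per-frame difference vectors child-minus-parent.
"""

import numpy as np

from skelemo import (build_upper_body_graph, joints_to_bones,
                     spatial_partition, SkeletonSequence)

graph = build_upper_body_graph()
print(f"joints ({graph.num_joints}):", ", ".join(graph.joint_names))
print(f"edges ({len(graph.edges)}):", graph.edges)
print("hop distance to centre:", graph.hop_distance_to_center().tolist())

part = spatial_partition(graph, normalize=False)
for name, subset in zip(("root", "centripetal", "centrifugal"), part.subsets):
    print(f"{name:12s} subset has {int(subset.sum())} nonzero entries")
# the three subsets tile A + I exactly: every (node, neighbour) pair is
# assigned to exactly one subset
total = part.subsets.sum(axis=0)
print("subsets tile A + I:", np.array_equal(total, graph.adjacency() + np.eye(10)))

# bones: a static 1-frame pose; each bone entry is child - parent
rng = np.random.default_rng(0)
pose = SkeletonSequence(coords=rng.normal(scale=0.3, size=(1, 10, 3)), label=0)
bones = joints_to_bones(pose, graph)
wrist = graph.joint_names.index("left_wrist")
print("left wrist bone vector (wrist - elbow):",
      np.round(bones.coords[0, wrist], 3))
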