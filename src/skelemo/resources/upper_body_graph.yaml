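# Default 10-joint upper-body skeleton graph.
# The spine base is retained as the body-centre joint for the
# spatial-configuration partitioning even though the rest of the lower
# body is excluded.
joint_names:
  - spine_base
  - spine_chest
  - neck
  - head
  - left_shoulder
  - right_shoulder
  - left_elbow
  - right_elbow
  - left_wrist
  - right_wrist
edges:
  - [0, 1]
  - [1, 2]
  - [2, 3]
  - [2, 4]
  - [2, 5]
  - [4, 6]
  - [5, 7]
  - [6, 8]
  - [7, 9]
center_joint: 0
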