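"""Reading and writing skeleton datasets and graph definitions.

Dataset format: JSON Lines, one object per sample with keys
``sample_id``, ``label``, ``frame_rate`` and ``coords`` (T×V×3 nested
lists).  A per-sample CSV reader (columns ``frame, joint, x, y, z``) is
also provided for data exported from pose-estimation tools.  Graph
definitions live in YAML with ``joint_names``, ``edges`` and
``center_joint``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import yaml

from .graph import SkeletonGraph, SkeletonSequence

__all__ = ["write_jsonl", "read_jsonl", "read_sample_csv",
           "load_graph_yaml", "save_graph_yaml", "default_graph_path"]


def default_graph_path() -> Path:
    """Path of the shipped 10-joint upper-body graph definition."""
    return Path(__file__).parent / "resources" / "upper_body_graph.yaml"


def write_jsonl(path, seqs: list[SkeletonSequence]) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(json.dumps({
                "sample_id": seq.sample_id,
                "label": int(seq.label),
                "frame_rate": seq.frame_rate,
                "coords": seq.coords.tolist(),
            }) + "\n")


def read_jsonl(path) -> list[SkeletonSequence]:
    seqs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            seqs.append(SkeletonSequence(
                coords=np.asarray(obj["coords"], dtype=float),
                label=int(obj["label"]),
                sample_id=obj.get("sample_id", ""),
                frame_rate=float(obj.get("frame_rate", 30.0)),
            ))
    return seqs


def read_sample_csv(path, label: int = -1, frame_rate: float = 30.0,
                    sample_id: str | None = None) -> SkeletonSequence:
    """Read one sample from a ``frame, joint, x, y, z`` CSV file."""
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            rows.append((int(row["frame"]), int(row["joint"]),
                         float(row["x"]), float(row["y"]), float(row["z"])))
    if not rows:
        raise ValueError(f"{path}: no rows")
    t = max(r[0] for r in rows) + 1
    v = max(r[1] for r in rows) + 1
    coords = np.full((t, v, 3), np.nan)
    for frame, joint, x, y, z in rows:
        coords[frame, joint] = (x, y, z)
    if np.isnan(coords).any():
        missing = int(np.isnan(coords[..., 0]).sum())
        raise ValueError(f"{path}: {missing} (frame, joint) cells missing")
    return SkeletonSequence(coords=coords, label=label, frame_rate=frame_rate,
                            sample_id=sample_id or Path(path).stem)


def save_graph_yaml(path, graph: SkeletonGraph) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "joint_names": list(graph.joint_names or
                                [f"joint_{i}" for i in range(graph.num_joints)]),
            "edges": [list(e) for e in graph.edges],
            "center_joint": graph.center_joint,
        }, fh, sort_keys=False)


def load_graph_yaml(path) -> SkeletonGraph:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    names = obj["joint_names"]
    return SkeletonGraph(num_joints=len(names),
                         edges=tuple(tuple(e) for e in obj["edges"]),
                         center_joint=int(obj["center_joint"]),
                         joint_names=tuple(names))
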