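"""Two-stream (joint + bone) score fusion and the multimodal late-fusion head.

The joint-input and bone-input networks are trained independently; at
test time their softmax score vectors are combined either by

* **summation** — element-wise addition of the two score vectors,
  argmax over the sum (lowest class index on exact ties), or
* **a trained fully connected layer** — the two score vectors are
  concatenated and passed through one linear layer trained with
  cross-entropy (typically on development-set scores).

For multimodal late fusion, fixed-length per-modality embedding vectors
(e.g. the pooled skeleton feature, plus externally computed audio/text
embeddings) each pass through their own linear layer; the projections
are concatenated and a linear output layer produces class probabilities.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, cross_entropy
from .metrics import evaluate_predictions
from .nn import DTYPE, Linear, Module, SGD

__all__ = ["align_scores", "two_stream_fuse_sum", "FusionHead",
           "two_stream_fuse_fc", "MultimodalHead", "multimodal_fusion_head"]


def align_scores(ids_a: list[str], scores_a: np.ndarray,
                 ids_b: list[str], scores_b: np.ndarray) -> np.ndarray:
    """Reorder stream B's scores to stream A's sample order."""
    if sorted(ids_a) != sorted(ids_b):
        only_a = set(ids_a) - set(ids_b)
        only_b = set(ids_b) - set(ids_a)
        raise ValueError(f"sample id mismatch: only in A {sorted(only_a)[:5]}, "
                         f"only in B {sorted(only_b)[:5]}")
    pos = {sid: i for i, sid in enumerate(ids_b)}
    return scores_b[[pos[sid] for sid in ids_a]]


def two_stream_fuse_sum(scores_joint: np.ndarray, scores_bone: np.ndarray,
                        ids_joint: list[str] | None = None,
                        ids_bone: list[str] | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sum softmax scores of the two streams; argmax prediction.

    Returns ``(fused_scores, predictions)``.  ``np.argmax`` resolves
    exact ties toward the lowest class index.
    """
    if ids_joint is not None and ids_bone is not None:
        scores_bone = align_scores(ids_joint, scores_joint, ids_bone, scores_bone)
    if scores_joint.shape != scores_bone.shape:
        raise ValueError(f"score shapes differ: {scores_joint.shape} vs "
                         f"{scores_bone.shape}")
    fused = scores_joint + scores_bone
    return fused, np.argmax(fused, axis=1)


class FusionHead(Module):
    """One linear layer on the concatenated 2×C score vector."""

    def __init__(self, num_classes: int, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.num_classes = num_classes
        self.linear = Linear(2 * num_classes, num_classes, rng)

    @classmethod
    def summation_init(cls, num_classes: int) -> "FusionHead":
        """Weights [I; I] so the head reproduces summation fusion exactly."""
        head = cls(num_classes, rng=0)
        eye = np.eye(num_classes, dtype=DTYPE)
        head.linear.weight.data = np.concatenate([eye, eye], axis=0)
        head.linear.bias.data = np.zeros(num_classes, dtype=DTYPE)
        return head

    def _concat(self, scores_joint: np.ndarray, scores_bone: np.ndarray) -> np.ndarray:
        return np.concatenate([scores_joint, scores_bone], axis=1).astype(DTYPE)

    def predict_proba(self, scores_joint: np.ndarray,
                      scores_bone: np.ndarray) -> np.ndarray:
        logits = self.linear(Tensor(self._concat(scores_joint, scores_bone)))
        return logits.softmax(axis=-1).data

    def predict(self, scores_joint: np.ndarray, scores_bone: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(scores_joint, scores_bone), axis=1)

    def fit(self, scores_joint: np.ndarray, scores_bone: np.ndarray,
            labels: np.ndarray, epochs: int = 300, lr: float = 0.1,
            seed: int = 0) -> "FusionHead":
        """Full-batch cross-entropy training of the fusion layer."""
        x = self._concat(scores_joint, scores_bone)
        y = np.asarray(labels)
        opt = SGD(self.parameters(), lr=lr, momentum=0.9)
        for _ in range(epochs):
            opt.zero_grad()
            loss = cross_entropy(self.linear(Tensor(x)), y)
            if not np.isfinite(loss.data):
                raise RuntimeError("fusion head training diverged")
            loss.backward()
            opt.step()
        return self


def two_stream_fuse_fc(scores_joint_train: np.ndarray,
                       scores_bone_train: np.ndarray,
                       labels_train: np.ndarray,
                       scores_joint_test: np.ndarray,
                       scores_bone_test: np.ndarray,
                       seed: int = 0,
                       epochs: int = 300) -> tuple[FusionHead, np.ndarray]:
    """Train the FC fusion head and predict on the test scores.

    The head is initialized at the summation-equivalent weights, so with
    zero training it reduces to summation fusion; training can only move
    away from that point if the data supports it.
    """
    head = FusionHead.summation_init(scores_joint_train.shape[1])
    head.fit(scores_joint_train, scores_bone_train, labels_train,
             epochs=epochs, seed=seed)
    return head, head.predict(scores_joint_test, scores_bone_test)


class MultimodalHead(Module):
    """Late-fusion classifier over per-modality embedding vectors.

    Each modality's fixed-length vector goes through its own linear
    projection; projections are concatenated and a linear output layer
    yields class probabilities.  Accepts any number >= 1 of modalities.
    """

    def __init__(self, modality_dims: list[int], num_classes: int,
                 proj_dim: int = 32, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        if not modality_dims:
            raise ValueError("need at least one modality")
        self.proj = [Linear(d, proj_dim, rng) for d in modality_dims]
        self.out = Linear(proj_dim * len(modality_dims), num_classes, rng)
        self.num_classes = num_classes

    def _forward(self, embeddings: list[np.ndarray]) -> Tensor:
        if len(embeddings) != len(self.proj):
            raise ValueError(f"expected {len(self.proj)} modalities, "
                             f"got {len(embeddings)}")
        n = {e.shape[0] for e in embeddings}
        if len(n) != 1:
            raise ValueError(f"modalities disagree on sample count: {sorted(n)}")
        parts = [layer(Tensor(np.asarray(e, dtype=DTYPE))).relu()
                 for layer, e in zip(self.proj, embeddings)]
        return self.out(_concat_tensors(parts))

    def predict_proba(self, embeddings: list[np.ndarray]) -> np.ndarray:
        return self._forward(embeddings).softmax(axis=-1).data

    def predict(self, embeddings: list[np.ndarray]) -> np.ndarray:
        return np.argmax(self._forward(embeddings).data, axis=1)

    def fit(self, embeddings: list[np.ndarray], labels: np.ndarray,
            epochs: int = 300, lr: float = 0.05, seed: int = 0) -> "MultimodalHead":
        y = np.asarray(labels)
        opt = SGD(self.parameters(), lr=lr, momentum=0.9)
        for _ in range(epochs):
            opt.zero_grad()
            loss = cross_entropy(self._forward(embeddings), y)
            if not np.isfinite(loss.data):
                raise RuntimeError("multimodal head training diverged")
            loss.backward()
            opt.step()
        return self


def _concat_tensors(parts: list[Tensor]) -> Tensor:
    """Concatenate tensors along axis 1 inside the autograd graph."""
    if len(parts) == 1:
        return parts[0]
    total = sum(p.shape[1] for p in parts)
    # build via padded sums so gradients route back to every part
    acc = None
    offset = 0
    for p in parts:
        width = p.shape[1]
        pad_spec = ((0, 0), (offset, total - offset - width))
        padded = _pad_cols(p, pad_spec, total)
        acc = padded if acc is None else acc + padded
        offset += width
    return acc


def _pad_cols(t: Tensor, pad_spec, total: int) -> Tensor:
    data = np.pad(t.data, pad_spec)
    (r0, r1), (c0, c1) = pad_spec

    def backward(g):
        t._accum(g[:, c0:g.shape[1] - c1] if c1 else g[:, c0:])

    return t._make(data, (t,), backward)


def multimodal_fusion_head(embeddings_train: list[np.ndarray],
                           labels_train: np.ndarray,
                           num_classes: int,
                           proj_dim: int = 32,
                           seed: int = 0,
                           epochs: int = 300) -> MultimodalHead:
    """Train a late-fusion classifier on per-modality embeddings."""
    head = MultimodalHead([e.shape[1] for e in embeddings_train], num_classes,
                          proj_dim=proj_dim, rng=seed)
    head.fit(embeddings_train, labels_train, epochs=epochs, seed=seed)
    return head
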