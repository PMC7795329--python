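"""Dataset splitting and the SGD training loop.

Training minimizes cross-entropy with stochastic gradient descent
(momentum 0.9, step-decayed learning rate) and selects the checkpoint
with the best development-set UAR.  The split follows an 8 : 0.5 : 1.5
train/dev/test ratio, stratified by label, with deterministic seeded
shuffling throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .autograd import cross_entropy
from .graph import SkeletonSequence
from .metrics import evaluate_predictions
from .network import SSTGCN
from .nn import DTYPE, SGD

__all__ = ["SplitSpec", "TrainConfig", "split_dataset", "sequences_to_array",
           "train_model"]


@dataclass(frozen=True)
class SplitSpec:
    """Train/dev/test split proportions (stored un-normalized)."""

    ratios: tuple[float, float, float] = (8.0, 0.5, 1.5)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = sum(self.ratios)
        return tuple(r / total for r in self.ratios)


def _allocate(counts: np.ndarray, fractions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder allocation of per-stratum counts to 3 splits.

    Returns an (n_strata, 3) integer matrix whose rows sum to ``counts``
    and whose column totals match the fractions as closely as integer
    rounding allows (dev and test are rounded first, train absorbs the
    rest, mirroring how a fixed-size held-out set is usually carved out).
    """
    n_strata = len(counts)
    alloc = np.zeros((n_strata, 3), dtype=int)
    for col in (1, 2):  # dev, then test
        quota = counts * fractions[col]
        base = np.floor(quota).astype(int)
        remainder = quota - base
        short = int(round(quota.sum())) - base.sum()
        order = np.argsort(-remainder, kind="stable")  # ties: lowest stratum
        for i in order[:max(short, 0)]:
            base[i] += 1
        alloc[:, col] = base
    alloc[:, 0] = counts - alloc[:, 1] - alloc[:, 2]
    if (alloc < 0).any():
        raise ValueError("stratum too small for the requested split ratios")
    return alloc


def split_dataset(samples: list, spec: SplitSpec,
                  labels: np.ndarray | None = None):
    """Partition samples into (train, dev, test) lists.

    Deterministic given ``spec.seed``; stratified by label when
    ``spec.stratified`` (labels are read from ``sample.label`` unless
    passed explicitly).  The three parts are disjoint and cover the
    input exactly.
    """
    n = len(samples)
    if labels is None:
        labels = np.array([s.label for s in samples])
    else:
        labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    fractions = spec.fractions
    if spec.stratified:
        classes = np.unique(labels)
        counts = np.array([(labels == c).sum() for c in classes])
        if (counts == 0).any():
            raise ValueError("every class needs at least one sample")
        alloc = _allocate(counts, fractions)
        parts: tuple[list, list, list] = ([], [], [])
        for c, row in zip(classes, alloc):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            # order within each class: train, dev, test
            chunks = np.split(idx, [row[0], row[0] + row[1]])
            for part, chunk in zip(parts, chunks):
                part.extend(samples[i] for i in chunk)
        return parts
    idx = rng.permutation(n)
    alloc = _allocate(np.array([n]), fractions)[0]
    chunks = np.split(idx, [alloc[0], alloc[0] + alloc[1]])
    return tuple([samples[i] for i in chunk] for chunk in chunks)


def sequences_to_array(seqs: list[SkeletonSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-length sequences into an (N, 3, T, V) float32 batch."""
    lengths = {s.num_frames for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have mixed lengths {sorted(lengths)}; apply "
            "standardize_length first")
    x = np.stack([s.coords.transpose(2, 0, 1) for s in seqs]).astype(DTYPE)
    y = np.array([s.label for s in seqs], dtype=int)
    return x, y


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (SGD with momentum, step decay)."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 16
    epochs: int = 200
    lr_decay: float = 0.1
    lr_decay_epochs: tuple[int, ...] = ()
    seed: int = 0
    target_train_accuracy: float | None = None  # optional early stop
    verbose: bool = False


def train_model(train: tuple[np.ndarray, np.ndarray],
                dev: tuple[np.ndarray, np.ndarray] | None,
                model: SSTGCN,
                cfg: TrainConfig = TrainConfig(),
                ) -> tuple[SSTGCN, list[dict]]:
    """Train in place; returns the model and a per-epoch history.

    When a dev set is given, the parameter state with the best dev UAR
    is restored at the end (epoch ties keep the earlier state).  Raises
    ``RuntimeError`` on a non-finite loss.
    """
    x_train, y_train = train
    if len(y_train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_uar, best_state = -1.0, None
    n = len(y_train)
    for epoch in range(cfg.epochs):
        if epoch in cfg.lr_decay_epochs:
            opt.lr *= cfg.lr_decay
        model.train()
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            opt.zero_grad()
            logits = model.logits(xb)
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={float(loss.data)}; "
                    "lower the learning rate")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((np.argmax(logits.data, axis=1) == yb).sum())
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "train_accuracy": correct / n, "lr": opt.lr}
        model.eval()
        if dev is not None and len(dev[1]) > 0:
            x_dev, y_dev = dev
            report = evaluate_predictions(y_dev, model.predict(x_dev),
                                          model.cfg.num_classes)
            record["dev_uar"] = report.uar
            record["dev_war"] = report.war
            if report.uar > best_uar:
                best_uar = report.uar
                best_state = copy.deepcopy(model.state_arrays())
        history.append(record)
        if cfg.verbose:
            print(f"epoch {epoch:3d} loss {record['train_loss']:.4f} "
                  f"acc {record['train_accuracy']:.3f}"
                  + (f" dev_uar {record.get('dev_uar', float('nan')):.3f}"
                     if dev is not None else ""))
        if (cfg.target_train_accuracy is not None
                and record["train_accuracy"] >= cfg.target_train_accuracy):
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history
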