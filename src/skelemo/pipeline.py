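"""End-to-end experiment drivers tying the pieces together.

These helpers run the full study on a dataset of labelled skeleton
sequences: preprocessing (low-pass filter + length standardization),
8 : 0.5 : 1.5 stratified splitting, independent training of the
joint-input and bone-input streams, and two-stream fusion with both
strategies.  They are what the command-line interface, the examples and
the acceptance script call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import SkeletonGraph, SkeletonSequence, build_upper_body_graph, \
    joints_to_bones, spatial_partition
from .metrics import EvalReport, evaluate_predictions
from .network import ModelConfig, SSTGCN
from .preprocessing import FilterConfig, LengthPolicy, lowpass_filter_sequence, \
    standardize_length
from .training import SplitSpec, TrainConfig, sequences_to_array, split_dataset, \
    train_model
from .fusion import two_stream_fuse_fc, two_stream_fuse_sum

__all__ = ["ExperimentConfig", "preprocess_sequences", "prepare_streams",
           "train_stream", "run_two_stream_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun a two-stream experiment."""

    model: ModelConfig = field(default_factory=ModelConfig.benchmark)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=16, lr=0.05, lr_decay_epochs=(10, 14), batch_size=16))
    split: SplitSpec = field(default_factory=SplitSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    length: LengthPolicy = field(default_factory=lambda: LengthPolicy(
        target_length=48, mode="resample"))
    apply_filter: bool = True
    seed: int = 0


def preprocess_sequences(seqs: list[SkeletonSequence],
                         cfg: ExperimentConfig) -> list[SkeletonSequence]:
    """Low-pass filter (optional) then standardize length."""
    out = []
    for seq in seqs:
        if cfg.apply_filter:
            seq = lowpass_filter_sequence(seq, cfg.filter)
        out.append(standardize_length(seq, cfg.length))
    return out


def prepare_streams(seqs: list[SkeletonSequence], graph: SkeletonGraph,
                    cfg: ExperimentConfig):
    """Preprocess and split; returns per-stream (train, dev, test) arrays.

    The split is computed once on the joint sequences and mirrored to
    the bone stream, so both streams see the same partition.
    """
    processed = preprocess_sequences(seqs, cfg)
    split_idx = split_dataset(list(range(len(processed))), cfg.split,
                              labels=np.array([s.label for s in processed]))
    streams = {}
    for name in ("joint", "bone"):
        if name == "joint":
            stream_seqs = processed
        else:
            stream_seqs = [joints_to_bones(s, graph) for s in processed]
        streams[name] = tuple(
            sequences_to_array([stream_seqs[i] for i in part])
            for part in split_idx
        )
    return streams


def train_stream(data, graph: SkeletonGraph, cfg: ExperimentConfig,
                 seed: int) -> tuple[SSTGCN, list[dict], EvalReport]:
    """Train one stream on (train, dev, test) arrays; evaluate on test."""
    train, dev, test = data
    adj = spatial_partition(graph)
    model = SSTGCN(cfg.model, adj, rng=seed)
    train_cfg = TrainConfig(**{**cfg.train.__dict__, "seed": seed})
    model, history = train_model(train, dev, model, train_cfg)
    x_test, y_test = test
    report = evaluate_predictions(y_test, model.predict(x_test),
                                  cfg.model.num_classes)
    return model, history, report


def run_two_stream_experiment(seqs: list[SkeletonSequence],
                              cfg: ExperimentConfig,
                              graph: SkeletonGraph | None = None) -> dict:
    """Full study: both streams + summation and FC fusion.

    Returns a dict with per-stream test reports, fusion reports, and the
    trained models.  The FC fusion head is trained on dev-set scores.
    """
    graph = graph or build_upper_body_graph()
    streams = prepare_streams(seqs, graph, cfg)
    results: dict = {"reports": {}, "models": {}, "history": {}}
    scores = {}
    for name in ("joint", "bone"):
        model, history, report = train_stream(streams[name], graph, cfg, cfg.seed)
        results["models"][name] = model
        results["history"][name] = history
        results["reports"][name] = report
        scores[name] = {
            "dev": model(streams[name][1][0]).data,
            "test": model(streams[name][2][0]).data,
        }
    y_dev = streams["joint"][1][1]
    y_test = streams["joint"][2][1]
    num_classes = cfg.model.num_classes

    _, preds_sum = two_stream_fuse_sum(scores["joint"]["test"],
                                       scores["bone"]["test"])
    results["reports"]["fusion_sum"] = evaluate_predictions(
        y_test, preds_sum, num_classes)

    head, preds_fc = two_stream_fuse_fc(
        scores["joint"]["dev"], scores["bone"]["dev"], y_dev,
        scores["joint"]["test"], scores["bone"]["test"], seed=cfg.seed)
    results["models"]["fusion_fc"] = head
    results["reports"]["fusion_fc"] = evaluate_predictions(
        y_test, preds_fc, num_classes)
    return results
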