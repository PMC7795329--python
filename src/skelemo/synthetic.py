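"""Class-conditional synthetic skeleton sequences.

Generates labelled upper-body motion so the whole pipeline — filtering,
graph construction, the two-stream network, fusion and evaluation — can
be exercised end to end without any recorded data.  Each emotion class
perturbs a common rest pose with its own posture offsets and oscillation
dynamics, loosely modelled on how the classes differ kinematically in
expressive movement:

* ``neutral`` — small-amplitude slow sway around the rest pose;
* ``happy``  — raised arms with moderate-amplitude arm oscillation;
* ``sad``    — forward spine lean and lowered head, low overall velocity;
* ``angry``  — high-amplitude, high-frequency wrist/elbow oscillation.

``effect_scale`` linearly interpolates every class-specific parameter
between the neutral signature (scale 0, all classes statistically
identical) and the full signature (scale 1); values above 1 exaggerate
the separation.  On top of the clean trajectory the generator adds white
positional noise and a sinusoidal high-frequency jitter emulating
pose-estimation error, which the low-pass preprocessing is meant to
remove.

These signatures are synthetic constructs for testing, not measurements
of any motion-capture corpus.  Units are meters; the rest pose spans
roughly 0.5 m pelvis-to-shoulder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SkeletonGraph, SkeletonSequence, build_upper_body_graph

__all__ = ["GeneratorSpec", "generate_dataset", "generate_sample",
           "make_tiny_fixture", "CLASS_NAMES"]

CLASS_NAMES = ("neutral", "happy", "sad", "angry")

# rest pose for the 10-joint upper-body roster (x right, y up, z forward)
REST_POSE = np.array([
    [0.00, 0.00, 0.00],   # spine_base
    [0.00, 0.30, 0.00],   # spine_chest
    [0.00, 0.50, 0.00],   # neck
    [0.00, 0.68, 0.00],   # head
    [0.18, 0.48, 0.00],   # left_shoulder
    [-0.18, 0.48, 0.00],  # right_shoulder
    [0.28, 0.22, 0.02],   # left_elbow
    [-0.28, 0.22, 0.02],  # right_elbow
    [0.30, 0.00, 0.08],   # left_wrist
    [-0.30, 0.00, 0.08],  # right_wrist
])

_WRISTS = (8, 9)
_ELBOWS = (6, 7)
_SHOULDERS = (4, 5)
_SPINE_HEAD = {1: (0.00, -0.02, 0.05),   # chest leans forward
               2: (0.00, -0.04, 0.09),
               3: (0.00, -0.10, 0.16)}   # head drops and comes forward

# per-class kinematic signature:
#   arm_amp (m), arm_freq (Hz) for wrist oscillation (elbows at half
#   amplitude, shoulders at 0.15x), body_amp/body_freq for whole-body
#   sway, and posture offsets (m) added to the rest pose.
_SIGNATURES: dict[str, dict] = {
    "neutral": dict(arm_amp=0.015, arm_freq=0.8, body_amp=0.010,
                    body_freq=0.5, offsets={}),
    "happy": dict(arm_amp=0.050, arm_freq=1.6, body_amp=0.012,
                  body_freq=0.6,
                  offsets={6: (0.0, 0.10, 0.0), 7: (0.0, 0.10, 0.0),
                           8: (0.0, 0.22, 0.05), 9: (0.0, 0.22, 0.05)}),
    "sad": dict(arm_amp=0.006, arm_freq=0.3, body_amp=0.005,
                body_freq=0.3, offsets=_SPINE_HEAD),
    "angry": dict(arm_amp=0.090, arm_freq=3.5, body_amp=0.020,
                  body_freq=1.2, offsets={}),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of the synthetic benchmark."""

    num_per_class: int = 100
    classes: tuple[str, ...] = CLASS_NAMES
    t_range: tuple[int, int] = (90, 150)
    frame_rate: float = 30.0
    noise_sd: float = 0.004
    hf_noise_sd: float = 0.010
    hf_freq: float = 12.0
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.noise_sd, self.hf_noise_sd) < 0:
            raise ValueError("noise scales must be >= 0")
        lo, hi = self.t_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid t_range {self.t_range}")
        unknown = set(self.classes) - set(_SIGNATURES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


def _blend(class_name: str, scale: float) -> dict:
    """Interpolate a class signature between neutral (0) and full (1)."""
    base, sig = _SIGNATURES["neutral"], _SIGNATURES[class_name]
    out = {k: base[k] + scale * (sig[k] - base[k])
           for k in ("arm_amp", "arm_freq", "body_amp", "body_freq")}
    out["offsets"] = {j: scale * np.asarray(off) for j, off in sig["offsets"].items()}
    return out


def generate_sample(rng: np.random.Generator, class_name: str,
                    spec: GeneratorSpec, sample_id: str = "",
                    ) -> tuple[SkeletonSequence, np.ndarray]:
    """Draw one noisy sequence; also returns the clean (noise-free) coords."""
    sig = _blend(class_name, spec.effect_scale)
    t = int(rng.integers(spec.t_range[0], spec.t_range[1] + 1))
    time = np.arange(t) / spec.frame_rate
    v = REST_POSE.shape[0]

    pose = REST_POSE.copy()
    for j, off in sig["offsets"].items():
        pose[j] += off
    clean = np.tile(pose, (t, 1, 1))

    # whole-body sway: one horizontal-plane sinusoid shared by all joints
    sway_dir = rng.normal(size=3) * np.array([1.0, 0.2, 1.0])
    sway_dir /= np.linalg.norm(sway_dir) + 1e-12
    phase = rng.uniform(0, 2 * np.pi)
    sway = sig["body_amp"] * np.sin(2 * np.pi * sig["body_freq"] * time + phase)
    clean += sway[:, None, None] * sway_dir[None, None, :]

    # arm oscillation: random direction and phase per joint
    for joints, rel_amp in ((_WRISTS, 1.0), (_ELBOWS, 0.5), (_SHOULDERS, 0.15)):
        for j in joints:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction) + 1e-12
            amp = sig["arm_amp"] * rel_amp * rng.uniform(0.8, 1.2)
            phase = rng.uniform(0, 2 * np.pi)
            osc = amp * np.sin(2 * np.pi * sig["arm_freq"] * time + phase)
            clean[:, j, :] += osc[:, None] * direction[None, :]

    # pose-estimation-like corruption: white noise + high-frequency jitter
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    hf_phase = rng.uniform(0, 2 * np.pi, size=(v, 3))
    jitter = spec.hf_noise_sd * np.sin(
        2 * np.pi * spec.hf_freq * time[:, None, None] + hf_phase[None])
    noisy = noisy + jitter

    label = list(spec.classes).index(class_name)
    seq = SkeletonSequence(coords=noisy, label=label, sample_id=sample_id,
                           frame_rate=spec.frame_rate)
    return seq, clean


def generate_dataset(spec: GeneratorSpec, with_clean: bool = False):
    """Generate ``num_per_class`` sequences per class, fully seeded.

    Returns a list of :class:`SkeletonSequence`; with ``with_clean=True``
    also returns the parallel list of noise-free coordinate arrays.
    """
    rng = np.random.default_rng(spec.seed)
    seqs, cleans = [], []
    for label, name in enumerate(spec.classes):
        for i in range(spec.num_per_class):
            seq, clean = generate_sample(rng, name, spec, f"{name}_{i:03d}")
            seqs.append(seq)
            cleans.append(clean)
    return (seqs, cleans) if with_clean else seqs


def make_tiny_fixture() -> tuple[SkeletonGraph, list[SkeletonSequence]]:
    """A 3-joint chain and 8 hand-written 2-frame sequences.

    The chain is centre ``c=0`` — ``a=1`` — ``b=2``, so the bone
    decomposition and the adjacency partition can be enumerated by hand
    and used as an exact oracle.
    """
    graph = SkeletonGraph(num_joints=3, edges=((0, 1), (1, 2)), center_joint=0,
                          joint_names=("c", "a", "b"))
    seqs = []
    for i in range(8):
        base = float(i)
        coords = np.array([
            [[0.0, 0.0, 0.0], [1.0 + base, 0.0, 0.0], [2.0 + base, 1.0, 0.0]],
            [[0.0, 0.5, 0.0], [1.0 + base, 0.5, 0.0], [2.0 + base, 2.0, 0.0]],
        ])
        seqs.append(SkeletonSequence(coords=coords, label=i % 4,
                                     sample_id=f"tiny_{i}", frame_rate=30.0))
    return graph, seqs
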