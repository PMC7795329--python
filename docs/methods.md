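# Methods

## Problem setting

A sample is a variable-length sequence of 3D positions of V = 10
upper-body joints (spine base, spine/chest, neck, head, left/right
shoulder, elbow, wrist) with one categorical emotion label in
{neutral, happy, sad, angry}. Pose-estimation pipelines that produce
such sequences leave high-frequency detection jitter on the
trajectories and are unreliable for the lower body, which motivates
both the low-pass preprocessing and the upper-body-only graph. The
joint roster itself is a convention: common pose estimators disagree on
keypoint sets, so the graph is configurable (YAML definition file,
`skelemo/resources/upper_body_graph.yaml` is the shipped default) and
the spine base is retained as the body-centre node even though the rest
of the lower body is dropped — the centre is what the partitioning
strategy and the bone decomposition are defined against.

## Model

Each of the stacked blocks applies a self-attention enhanced spatial
graph convolutional layer, then a `(K_t, 1)` temporal convolution.

The **graph-convolutional branch** uses the spatial-configuration
partition of A + I into root / centripetal / centrifugal subsets, one
trainable 1×1-convolution weight block and one trainable element-wise
mask M_k (initialized to ones) per subset. Neighbours at equal distance
from the centre — impossible on a tree, possible on general graphs —
are assigned centripetally, a deterministic tie-break. Each subset is
symmetrically degree-normalized, `D_k^{-1/2} A_k D_k^{-1/2}`, with an
ε = 1e−6 pseudo-degree on empty rows to avoid division by zero.

The **attention branch** runs multi-head scaled dot-product attention
over joints independently per frame with frame-shared weights, so it can
route information between any pair of joints based on their current
features; a residual (projected by W_R when C_in ≠ C_out) stabilizes it.
The **gate** r (one trainable scalar per layer, initialized at 1)
weights the attention branch before the two branches are averaged:
`f_out = (f_g + r·f_a)/2`. Setting `gated=False` freezes r at 1, which
is the ablation variant; at r = 0 the model provably ignores every
attention parameter (this is a test).

Block layout: S-SGC → batch norm → ReLU → temporal conv (stride 1 or 2,
symmetric padding, T′ = ⌈T/stride⌉) → batch norm → dropout → add a
block-level residual (identity, or a strided 1×1 projection + batch
norm when the shape changes) → ReLU. The input is normalized by a batch
norm over the flattened (channel, joint) trajectories. After the last
block, global average pooling over time and joints gives the sample
embedding; a linear layer produces class scores. The training loss
consumes pre-softmax scores; `model(x)` returns probabilities.

Both the attention residual and the block-level residual are present;
with channel-preserving blocks they are redundant in expressivity but
cheap, and keeping both matches the layer/block structure as described.

### Architecture defaults

| parameter | default | note |
|---|---|---|
| channel plan | 32,32,32,32,64,64,64,128,128,128 | the 10-block configuration |
| temporal kernel K_t | 9 | odd; receptive field (K_t, 1) |
| temporal strides | 2 at the two channel-doubling blocks (5, 8) | halves T twice |
| heads H | 4 | d_k = d_v = C_out/H per layer |
| dropout | 0.5 | after the temporal conv |
| gate r | trainable, init 1 | one scalar per layer |

H, d_k/d_v, K_t, strides, normalization and dropout placement are not
pinned down by the model definition itself; these defaults follow the
conventions of the ST-GCN family and are all configurable through
`ModelConfig`. Two reduced stacks are provided for CPU-scale work:
`ModelConfig.benchmark()` (4 blocks, 16/16/32/32, K_t = 5, H = 2,
stride 2 at block 3, dropout 0.1) and `ModelConfig.tiny()` (2 blocks,
for smoke tests and examples).

## Preprocessing

Zero-phase (forward-backward) Butterworth low-pass filtering, default
order 4 and 6 Hz cutoff at 30 fps, applied independently to every
joint/axis trajectory. Human voluntary movement concentrates below
~6 Hz while estimation jitter is broadband, and zero-phase filtering
avoids the temporal lag that would distort movement dynamics; the
effective magnitude response is |H(f)|², which the tests check against
the analytic filter response. Filtering is applied to the 3D
trajectories this package ingests (not to 2D detections, which are out
of its scope). Sequences shorter than `3·(order+1)+1` frames are
rejected with the minimum stated.

Variable-length clips are standardized to `T_fix` frames for batching:
cyclic repetition, zero padding, or linear-interpolation resampling
(default; T_fix = 128 generally, 48 for the reduced benchmark so the
two stride-2 stages stay well defined).

## Training and evaluation

SGD with momentum 0.9, batch size 16, cross-entropy loss, step-decayed
learning rate; every random choice (init, shuffling, dropout) derives
from explicit seeds, and two runs with the same seeds produce
bit-identical losses. The 8 : 0.5 : 1.5 train/dev/test split is
stratified by label using largest-remainder allocation (so 1000 samples
give exactly 800/50/150) and seeded; the checkpoint with the best dev
UAR is kept. The split is by sample, not by speaker/session — a real
corpus protocol would need a grouping the synthetic data does not have.

UAR is the mean of per-class recalls (classes absent from the
evaluation set are excluded with a warning); WAR equals accuracy. Exact
argmax ties resolve to the lowest class index.

Two-stream fusion: summation of softmax scores, or one fully connected
layer on the concatenated 2×C scores, trained with cross-entropy on
development-set scores after both streams have converged. The FC head
is initialized at paired-identity weights, the exact summation
equivalent, so training starts from the summation baseline. The
multimodal head accepts any number of fixed-length per-modality
embedding vectors (per-modality linear projection, default width 32 →
concatenation → linear output layer); the skeleton embedding is the
pooled feature before the output layer. Audio/text encoders are outside
this package's scope — their embeddings are inputs.

## Synthetic data generator

The generator emulates the *output* of a pose-extraction pipeline:
per-frame 3D joint positions with class-dependent posture and dynamics
plus estimation noise. Each class perturbs a common rest pose (meters;
pelvis-to-shoulder ≈ 0.5 m) with its own signature — angry:
high-amplitude (0.09 m), high-frequency (3.5 Hz) wrist/elbow
oscillation; happy: raised arms with moderate oscillation (0.05 m,
1.6 Hz); sad: forward spine lean, lowered head, low velocity; neutral:
small slow sway. `effect_scale` interpolates every signature linearly
between the neutral parameters (scale 0: classes statistically
identical, so any classifier's expected UAR is 0.25) and the full
signature (scale 1). Corruption is additive white noise (sd 0.004 m)
plus a 12 Hz sinusoidal jitter (amplitude 0.01 m) sitting above the
filter cutoff and below Nyquist, so preprocessing demonstrably removes
it. Clip lengths are drawn uniformly from 90–150 frames at 30 fps.

What the generator does **not** emulate: realistic biomechanics (no
joint-angle constraints, no bone-length rigidity under oscillation),
occlusion artifacts and outlier detections, speaker identity and
dialogue context, and class overlap as messy as real acted-emotion
corpora. Passing the benchmark therefore shows that the implementation
can learn class-conditional posture/dynamics signatures end to end —
not that it would reach any particular accuracy on real data, where
reported accuracies are far from perfect.

## Benchmark problem sizes

The default synthetic benchmark trains on 100 samples/class with the
4-block reduced stack at T_fix = 48 for 16 epochs (decay at 10 and 14),
three seeds; the overfit-capacity check uses 40 samples with up to 200
epochs and early stop at 95% training accuracy; the label-shuffle
control permutes training and dev labels and expects chance-level test
UAR. The monotonicity property (test UAR non-decreasing in
effect_scale) is checked at a further reduced scale (40 samples/class,
2-block stack, two seeds) — these sizes are the package's own choices
to keep everything comfortably runnable on one CPU.

## Numerical choices and degenerate inputs

Float32 parameters and activations throughout; attention logits use the
standard max-shift before softmax; cross-entropy is computed via a
shifted log-sum-exp. Batch-norm running statistics (momentum 0.1) back
evaluation mode — an untrained model evaluated before any training pass
can saturate its softmax, which is why examples and tests warm the
statistics by training first. Empty partition rows, disconnected
graphs (error names the unreachable joints), non-tree parent ambiguity,
mixed-length batches, absent evaluation classes and non-finite losses
(abort with diagnostic) are all handled explicitly.

## Known limitations

- No GPU path and no framework interop; the numpy engine is single
  threaded apart from BLAS and is sized for desk-scale experiments.
- The 10-block default at full T is slow on one CPU; the reduced stacks
  exist for exactly that reason.
- Real-data protocol features (speaker-disjoint splits, pose-estimation
  front end, audio/text encoders) are out of scope.
- The synthetic classes are far more separable at effect_scale 1 than
  real acted emotions; benchmark UARs near 1.0 should be read as a
  pipeline sanity check, not a performance claim.
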