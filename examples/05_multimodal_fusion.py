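"""Late fusion of the skeleton embedding with other modality embeddings.

The pooled feature vector before the network's output layer serves as
the skeleton embedding.  Here a second, synthetic modality carries
complementary class information (it only tells one class apart from the
rest), so the fused head can combine the strengths of both.
"""

import numpy as np

from skelemo import (ExperimentConfig, GeneratorSpec, LengthPolicy,
                     ModelConfig, SplitSpec, TrainConfig,
                     build_upper_body_graph, evaluate_predictions,
                     generate_dataset, multimodal_fusion_head)
from skelemo.pipeline import prepare_streams, train_stream

seqs = generate_dataset(GeneratorSpec(num_per_class=30, seed=0))
cfg = ExperimentConfig(
    model=ModelConfig.tiny(),
    train=TrainConfig(epochs=8, lr=0.05, seed=0),
    split=SplitSpec(seed=0),
    length=LengthPolicy(target_length=32, mode="resample"),
    seed=0,
)
graph = build_upper_body_graph()
streams = prepare_streams(seqs, graph, cfg)
model, _, report = train_stream(streams["joint"], graph, cfg, seed=0)

# skeleton embeddings: the pooled feature before the output layer
(x_tr, y_tr), _, (x_te, y_te) = streams["joint"]
emb_tr = model.features(x_tr).data
emb_te = model.features(x_te).data

# a synthetic second modality (think: a text embedding) that only
# distinguishes the last class from the rest
rng = np.random.default_rng(1)
other_tr = rng.normal(size=(len(y_tr), 6))
other_te = rng.normal(size=(len(y_te), 6))
other_tr[:, 0] += np.where(y_tr == 3, 3.0, 0.0)
other_te[:, 0] += np.where(y_te == 3, 3.0, 0.0)

for name, mods_tr, mods_te in (
        ("skeleton only", [emb_tr], [emb_te]),
        ("other only", [other_tr], [other_te]),
        ("fused", [emb_tr, other_tr], [emb_te, other_te])):
    head = multimodal_fusion_head(mods_tr, y_tr, num_classes=4,
                                  proj_dim=8, seed=0)
    uar = evaluate_predictions(y_te, head.predict(mods_te), 4).uar
    print(f"{name:14s} test UAR {uar:.3f}")
print("(the fused head sees both embeddings and should match or beat "
      "the better single modality)")
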