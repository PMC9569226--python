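"""Cross-validated classification of a separable synthetic cohort.

Runs the whole pipeline — per-fold feature selection, layer-wise
autoencoder pretraining, NCC-regularised fusion training with prototype
loss, nearest-prototype prediction — under the rotating 5-fold 3:1:1
train/validation/test plan, at test-scale encoder widths.
"""

from mvconn.encoder import EncoderSpec
from mvconn.evaluation import ExperimentConfig, run_experiment
from mvconn.network import FusionSpec, TrainConfig
from mvconn.prototypes import LossConfig
from mvconn.synth import SynthConfig, generate_multiview

data, _ = generate_multiview(SynthConfig(effect=5.0, seed=0))
cfg = ExperimentConfig(
    encoder=EncoderSpec((16, 8, 8), pretrain=True, pretrain_epochs=30),
    fusion=FusionSpec(mode="fuse", position=3, K=8),
    loss=LossConfig(gamma=1.0, margin=1.0, lambda1=0.5, lambda2=0.1),
    train=TrainConfig(batch_size=32, learning_rate=1e-2, epochs=60, seed=0),
    seed=0,
)
result = run_experiment(data, cfg)

print("per-fold test metrics (%):")
for r, report in enumerate(result.per_fold):
    vals = report.as_dict()
    print("  fold", r, " ".join(f"{k}={v:.1f}" for k, v in vals.items()))
m = result.mean.as_dict()
print("mean over the 5 disjoint test folds:",
      " ".join(f"{k}={v:.1f}" for k, v in m.items()))
print("per-fold selected feature counts (one entry per view):",
      result.support_sizes)
print("final view-alignment (NCC regulariser) per fold:",
      [f"{v:.3f}" for v in result.mv_trace],
      "- positive values mean the views' fused features are correlated")
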