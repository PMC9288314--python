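"""Repeated-run evaluation: mean metrics and across-run variance.

Runs the pipeline over several seeds on a small study and prints the
aggregate report, including the population variance of accuracy that
measures model stability.
"""

from ecnnsvm import PipelineConfig, SynthSpec, generate, repeated_runs
from ecnnsvm.network import ECNNConfig

ds = generate(SynthSpec(n_samples=40, dims=(60, 60, 60, 60),
                        n_informative=(5, 5, 5, 5), effect_size=3.0,
                        minority_fraction=0.3, seed=11))
net = ECNNConfig(conv1_filters=16, conv2_filters=8, fc_hidden=8,
                 max_epochs=12, patience=4, batch_size=8)
cfg = PipelineConfig(top_k=6, n_trees=60, ecnn=net)

agg, rounds = repeated_runs(ds.blocks, ds.labels, cfg, seeds=[0, 1, 2])
print("per-round accuracies:", [f"{a:.3f}" for a in agg.per_run_accuracies])
print(f"mean accuracy {agg.accuracy:.3f}  recall {agg.recall:.3f} "
      f"f1 {agg.f1:.3f}")
print(f"accuracy variance {agg.variance:.5f}")
# Variance here is the population form over repeated full runs; 0 means
# every round produced the same test accuracy. Each round's confusion
# matrix is logged so every aggregate number can be recomputed.
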