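"""Run the complete E-CNN-SVM pipeline on a separable synthetic study.

Executes selection, fusion, balancing, five-fold early-stopped network
training, feature extraction and the SVM head in both leakage modes, and
prints the test-set metrics.
"""

from dataclasses import replace

from ecnnsvm import (PipelineConfig, SynthSpec, generate_separable,
                     run_pipeline)
from ecnnsvm.network import ECNNConfig

ds = generate_separable(SynthSpec(seed=0))
net = ECNNConfig(max_epochs=40, patience=8)
cfg = PipelineConfig(seed=1, ecnn=net)

for mode in ("paper", "safe"):
    res = run_pipeline(ds.blocks, ds.labels, replace(cfg, mode=mode))
    m = res.report
    print(f"{mode:5s} mode: accuracy {m.accuracy:.3f}  recall {m.recall:.3f} "
          f"f1 {m.f1:.3f}  confusion {res.cm.as_dict()}")
    print(f"   resampling: {res.resample_report['counts_before']} -> "
          f"{res.resample_report['counts_after_clean']}, "
          f"{res.resample_report['n_tomek_links']} links removed")
# 'paper' mode balances before splitting (the reference order, which leaks
# synthetic neighbors of test points into training); 'safe' mode splits
# first. On this strongly separable cohort both reach ~1.0; on marginal
# data the difference between them quantifies the leakage.
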