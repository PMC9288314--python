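"""Generate a synthetic four-source study and rank features per source.

Builds a 65-patient cohort with 10 planted informative features per omics
source, runs random-forest importance ranking on the CNV block, and shows
how many planted features land in the top of the ranking.
"""

import numpy as np

from ecnnsvm import SynthSpec, generate, rf_feature_importance

spec = SynthSpec(seed=42)
ds = generate(spec)
print(f"cohort: {spec.n_samples} samples, "
      f"{ds.labels.sum()} deaths / {(1 - ds.labels).sum()} survivors")
for block in ds.blocks:
    print(f"  {block.source_tag.value:9s} {block.n_features:5d} features")

block = ds.blocks[0]
imp = rf_feature_importance(block, ds.labels, n_trees=500, seed=0)
planted = set(ds.manifest.query("source_tag == 'CNV'")["feature_index"])
top10 = set(imp.ranking[:10])
print(f"\nCNV: {len(top10 & planted)}/10 planted features in the top-10 "
      f"importance ranking")
print("top-5 scores:", np.round(imp.scores[imp.ranking[:5]], 4))
# Scores are normalized impurity decreases (sum to 1 over all features);
# planted 2-sigma mean-shift features should dominate the ranking.
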