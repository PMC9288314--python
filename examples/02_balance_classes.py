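"""Balance an imbalanced fused dataset with SMOTE + TomekLink cleaning.

Shows class counts before and after each phase and how many boundary
pairs the cleaning step removed.
"""

import json

from ecnnsvm import (SmoteParams, SynthSpec, fuse_equal_weight, generate,
                     hybrid_balance, minmax_normalize, rf_feature_importance,
                     select_top_k)

# weak signal + a narrow fused space so the class boundary actually overlaps
ds = generate(SynthSpec(n_samples=65, dims=(200, 200, 200, 200),
                        n_informative=(5, 5, 5, 5), effect_size=0.5, seed=3))
selected = [select_top_k(rf_feature_importance(b, ds.labels, n_trees=200,
                                               seed=i), b, 2)
            for i, b in enumerate(ds.blocks)]
fused = minmax_normalize(fuse_equal_weight(selected, ds.labels))

balanced, report = hybrid_balance(fused, SmoteParams(k_neighbors=5, seed=0))
print(json.dumps(report, indent=2))
print(f"synthetic rows: {int(balanced.synthetic.sum())}")
# Phase 1 (SMOTE) interpolates minority samples up to parity; phase 2
# removes both members of every cross-class mutual-nearest pair, cleaning
# the class boundary that interpolation can blur.
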