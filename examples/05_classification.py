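"""Classify subjects from connectivity features with LASSO + SVM LOOCV.

Features are the N(N-1)/2 pairwise connection coefficients. Each
leave-one-out fold standardizes on its training subjects, screens features
with LASSO (penalty 0.05) and trains a linear SVM; pooled held-out scores
give the ROC AUC. Both network orders are evaluated.
"""

import numpy as np

from hofcnet import (
    CohortDesign,
    EffectSpec,
    build_features,
    compute_hofc,
    compute_lofc,
    generate_cohort,
    svm_loocv,
)
from hofcnet.validation import even_partition

design = CohortDesign(
    n_group_a=20, n_group_b=20, n_regions=20, n_timepoints=200,
    partition=even_partition(20),
    effects=[EffectSpec("SMN", -0.20)],
    seed=13,
)
subjects, _ = generate_cohort(design)
groups = [g for _, g in subjects]

for order in ("low", "high"):
    lofcs = [compute_lofc(ts) for ts, _ in subjects]
    mats = lofcs if order == "low" else [compute_hofc(cm) for cm in lofcs]
    feats = build_features(mats, groups)
    res = svm_loocv(feats, lam=0.05, positive_label="B")
    n_sel = np.mean([s.size for s in res.selected_per_fold])
    print(f"{order}-order features: AUC {res.auc:.2f}, "
          f"accuracy {res.accuracy:.1f}%, sensitivity {res.sensitivity:.1f}%, "
          f"specificity {res.specificity:.1f}%  "
          f"(mean {n_sel:.1f} features selected per fold)")
print("an AUC well above 0.5 shows the planted group difference is "
      "recoverable from individual connectivity patterns.")
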