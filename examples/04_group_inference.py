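"""Group inference on a cohort with a planted modular effect.

Generates a cohort in which group B's within-SMN correlations are lowered
by 0.25, then (1) compares intra-modular FC between groups with a
covariate-free adjusted test and (2) localizes the affected edges with the
network-based statistic (NBS).
"""

import numpy as np

from hofcnet import (
    CohortDesign,
    EffectSpec,
    ModulePartition,
    adjusted_group_test,
    compute_lofc,
    generate_cohort,
    intra_modular_fc,
    nbs,
)
from hofcnet.validation import even_partition

part_map = even_partition(20)
design = CohortDesign(
    n_group_a=30, n_group_b=30, n_regions=20, n_timepoints=200,
    partition=part_map, effects=[EffectSpec("SMN", -0.25)], seed=5,
)
subjects, truth = generate_cohort(design)
mats = [compute_lofc(ts) for ts, _ in subjects]
groups = np.array([g for _, g in subjects])
partition = ModulePartition(part_map)

print("intra-modular FC group comparison (t > 0 means higher in group B):")
for module in ("SMN", "DMN", "VN"):
    vals = np.array([intra_modular_fc(cm, partition)[module] for cm in mats])
    gc = adjusted_group_test(vals, groups, metric_name=module)
    print(f"  {module}: t = {gc.t_stat:+.2f}, p = {gc.p_value:.2e}")
print("only the SMN, where the effect was planted, should be significant.\n")

res = nbs(mats[:30], mats[30:], primary_alpha=0.01, n_perm=1000, seed=1)
idx = {l: i for i, l in enumerate(truth.region_labels)}
planted = {tuple(sorted((idx[a], idx[b]))) for a, b in truth.affected_edges}
for k, comp in enumerate(res.significant(0.05)):
    found = planted & {tuple(sorted(e)) for e in comp["edges"]}
    print(f"NBS component {k}: {int(comp['size'])} edges, "
          f"corrected p = {comp['corrected_p']:.4f}, "
          f"contains {len(found)}/6 planted edges")
print("the significant component should cover most of the 6 planted "
      "within-SMN edges.")
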