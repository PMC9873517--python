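"""Graph topology across the sparsity grid with small-world normalization.

Computes the raw global metrics (Cp, Lp, Eglob, Eloc) and the normalized
small-world metrics (gamma, lambda, sigma; ratios against degree-preserving
rewired nulls) at each sparsity level, then reduces each curve to its area
under the curve (AUC) — the per-subject scalar used in group comparisons.
"""

import numpy as np

from hofcnet import (
    CohortDesign,
    SparsityCurve,
    SparsityGrid,
    auc_over_sparsity,
    binarize_at_sparsity,
    compute_lofc,
    generate_cohort,
    global_graph_metrics,
    normalize_small_world,
)
from hofcnet.validation import even_partition

design = CohortDesign(
    n_group_a=1, n_group_b=1, n_regions=20, n_timepoints=230,
    partition=even_partition(20), seed=3,
)
(ts, _), *_ = generate_cohort(design)[0]
cm = compute_lofc(ts)

grid = SparsityGrid(levels=np.round(np.arange(10, 51, 5) / 100, 2))
sigmas, eglobs = [], []
print(" s     Cp     Lp   Eglob  gamma lambda sigma")
for s in grid:
    g = binarize_at_sparsity(cm, float(s))
    raw = global_graph_metrics(g)
    sw = normalize_small_world(g, n_null=20, seed=int(s * 1000))
    sigmas.append(sw.sigma)
    eglobs.append(raw.Eglob)
    print(f"{s:.2f}  {raw.Cp:.3f}  {raw.Lp:.3f}  {raw.Eglob:.3f}  "
          f"{sw.gamma:5.2f}  {sw.lam:5.2f}  {sw.sigma:5.2f}")

auc_sigma = auc_over_sparsity(SparsityCurve(grid, np.array(sigmas), "sigma"))
auc_eglob = auc_over_sparsity(SparsityCurve(grid, np.array(eglobs), "Eglob"))
print(f"\nAUC over sparsity: sigma {auc_sigma:.3f}, Eglob {auc_eglob:.3f}")
print("sigma > 1 across the grid indicates small-world organization "
      "(clustered like a lattice, short paths like a random graph).")
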