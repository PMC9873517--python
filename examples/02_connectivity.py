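"""Build low-order and high-order connectivity matrices for one subject.

LOFC(i, j) is the Pearson correlation of the region time series; HOFC(i, j)
is the Pearson correlation of the two regions' LOFC profiles (their rows of
the LOFC matrix with entries i and j excluded) — similarity of how the two
regions attach to the rest of the network.
"""

import numpy as np

from hofcnet import CohortDesign, binarize_at_sparsity, compute_hofc, compute_lofc, generate_cohort
from hofcnet.validation import even_partition

design = CohortDesign(
    n_group_a=1, n_group_b=1, n_regions=20, n_timepoints=230,
    partition=even_partition(20), seed=7,
)
(ts, _group), *_ = generate_cohort(design)[0]

lofc = compute_lofc(ts)
hofc = compute_hofc(lofc)

print(f"time series: T={ts.n_timepoints}, N={ts.n_regions}")
print(f"LOFC matrix {lofc.values.shape}, mean off-diagonal "
      f"{lofc.values[np.triu_indices(20, 1)].mean():.3f}")
print(f"HOFC matrix {hofc.values.shape}, mean off-diagonal "
      f"{hofc.values[np.triu_indices(20, 1)].mean():.3f}")
# two regions in the same module correlate strongly in both constructions
print(f"within-module pair ({ts.region_labels[0]}, {ts.region_labels[1]}): "
      f"LOFC {lofc.values[0, 1]:.3f}, HOFC {hofc.values[0, 1]:.3f}")
print(f"between-module pair ({ts.region_labels[0]}, {ts.region_labels[5]}): "
      f"LOFC {lofc.values[0, 5]:.3f}, HOFC {hofc.values[0, 5]:.3f}")

g = binarize_at_sparsity(hofc, 0.2)
print(f"binary HOFC graph at 20% sparsity: {g.n_edges} edges "
      f"(= round(0.2 * 190) strongest positive weights)")
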