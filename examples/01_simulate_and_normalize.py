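"""Generate a small synthetic cohort and normalize one cancer's counts.

Shows the two library-size scalings (TMM for within-cancer contrasts, UQ
for combined tumor matrices) and the low-expression filter.
"""

import numpy as np

from panconet import SyntheticConfig, generate_cohort
from panconet.normalization import filter_low_expressed, log_cpm, tmm_factors, uq_factors

cfg = SyntheticConfig(n_cancers=4, tumors_per_cancer=30, normals_per_cancer=8,
                      n_genes=800, n_shared_modules=2, shared_module_size=20,
                      private_module_size=12)
counts, samples, truth = generate_cohort(cfg, seed=1)

mat = counts["C1"]
tmm = tmm_factors(mat)
uq = uq_factors(mat)
print(f"C1: {mat.shape[0]} genes x {mat.shape[1]} samples")
print("TMM factors (first 5):", np.round(tmm.factors.head().to_numpy(), 4))
print("UQ  factors (first 5):", np.round(uq.factors.head().to_numpy(), 4))
# factors hover near 1 because the simulated libraries differ mostly in depth,
# which the library size itself absorbs; composition shifts move them off 1.

keep = filter_low_expressed(mat, tmm, cpm_floor=10, frac=0.5)
print(f"low-expression filter keeps {len(keep)}/{mat.shape[0]} genes "
      "(a gene is dropped when CPM<10 in more than half of samples)")

logcpm = log_cpm(mat.subset_genes(keep), tmm)
print("logCPM of the first gene, first 3 samples:",
      np.round(logcpm.values.iloc[0, :3].to_numpy(), 3))
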