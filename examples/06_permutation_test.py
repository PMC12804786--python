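"""Permutation test: are DEGs overrepresented among MITE-carrying genes?

DEG labels are reshuffled across the gene universe 1,000 times with the
MITE flags fixed; the empirical p-value is the add-one-smoothed fraction
of permutations reaching the observed association count.
"""

import numpy as np

from mitelink.permutation import gene_mite_flags, permutation_test

# 44-gene universe: 10 DEGs of which 9 carry a MITE; 12 MITE genes total
genes = [f"gene{i:04d}" for i in range(44)]
deg_ids = set(genes[:10])
mite_ids = set(genes[1:10]) | set(genes[40:43])
flags = gene_mite_flags(genes, deg_ids, mite_ids)

result = permutation_test(
    flags["is_deg"].to_numpy(), flags["has_mite"].to_numpy(),
    n_permutations=1000, seed=17, alpha=0.01)

print(f"universe: {result.n_genes} genes, {result.n_degs} DEGs, "
      f"{result.n_mite_genes} MITE-associated")
print(f"observed MITE/DEG associations: P_obs = {result.p_obs}")
print(f"null mean of permuted counts: {np.mean(result.p_i):.2f}")
print(f"empirical p = {result.p_value:.4g} "
      f"({'significant' if result.significant else 'not significant'} "
      f"at alpha = {result.alpha})")
# Nine observed associations against a null centred near 2.7 is far in
# the tail: the association between insertions and expression is not
# explained by gene-count chance.
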