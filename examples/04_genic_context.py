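"""Assign genic contexts to insertion points and test enrichment.

Contexts are 2 kb upstream, 5'UTR, CDS, intron, 3'UTR, 2 kb downstream
or intergenic.  Counts per superfamily feed a Pearson chi-squared
independence test; per-cell contributions are the bubble sizes of the
classic enrichment plot, and densities are standardised to each
category's cumulative genomic length.
"""

import tempfile
from pathlib import Path

from mitelink import genic_context as gc
from mitelink import insertions as ins
from mitelink import simulate

cfg = simulate.default_config(seed=1)
bundle = simulate.simulate_study(cfg)

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate.write_bundle(bundle, Path(tmp))
    models = gc.build_gene_models(paths["gff"], cfg.chromosome_lengths)

sites = ins.parse_signatures(bundle.signatures, bundle.families)
assignments = gc.assign_contexts(sites, models)
counts = gc.context_counts(assignments, sites)
print("superfamily x context counts:")
print(counts)

lengths = gc.cumulative_category_lengths(models)
dens = gc.standardized_density(counts, lengths, per=100_000)
print("\ninsertions per 100 kb of category length:")
print(dens.round(2))

genic = counts[list(gc.GENIC_CONTEXTS)]
genic = genic.loc[genic.sum(axis=1) > 0, genic.sum(axis=0) > 0]
enrich = gc.chi_squared_enrichment(genic)
print(f"\nchi2={enrich.chi2:.3f}, dof={enrich.dof}, p={enrich.p_value:.3g}")
print("per-cell contributions (sum to chi2):")
print(enrich.contributions.round(2))
# Large contributions flag superfamily/context combinations that deviate
# most from the independence expectation.
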