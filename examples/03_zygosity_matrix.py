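"""Build the insertion frequency matrix, classify zygosity, and summarise
concordance with external verification calls.

Reference insertions average their paired F/R signature frequencies;
frequency > 0.7 is a homozygous insertion, 0.3-0.7 heterozygous, < 0.3 a
homozygous empty site.
"""

from mitelink import insertions as ins
from mitelink import simulate

cfg = simulate.default_config(seed=1)
bundle = simulate.simulate_study(cfg)

sites = ins.parse_signatures(bundle.signatures, bundle.families)
zyg = ins.zygosity_matrix(sites, cfg.samples)
fam_counts, sup_counts, copies = ins.zygosity_counts(sites, cfg.samples)

print(f"{len(sites)} insertion sites x {len(cfg.samples)} samples")
print("\nper-superfamily calls:")
print(sup_counts)
print("\ncopies per sample (calls other than hom_empty):")
print(copies.to_string())

# Concordance summary in the style of a PCR-verification table: each pair
# is (in-silico call, external call); diagonal cells are correct calls.
pairs = [("hom_occupied", "hom_occupied")] * 10 + \
        [("het", "het")] * 3 + [("het", "hom_occupied")] * 2 + \
        [("hom_empty", "no_amplification")] * 1
table = ins.summarize_concordance(pairs)
print(f"\nverification demo: {table.percent_correct}% correct, "
      f"{table.percent_incorrect}% incorrect of {table.total} combinations")
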