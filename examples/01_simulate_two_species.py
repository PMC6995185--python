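"""Simulate two primate-like genomes carrying ERV-W-like insertions.

Builds the default two-species scenario (a colonisation wave spanning a
19-My species split, proviruses, solitary LTRs and a few processed
pseudogenes) and prints the ground truth the generator records for every
planted locus.
"""

from ervkit import simulate

result = simulate.make_genome(seed=1)

for species, genome in result.genomes.items():
    print(f"{species}: {len(genome):,} nt")
print()
print(result.truth.true_class.value_counts().to_string())
pairs = (result.truth.ortholog_partner != "").sum() // 2
print(f"\northologous insertion pairs (older than the split): {pairs}")
print("\nfirst loci with ground truth:")
cols = ["locus_id", "true_class", "true_age_my", "true_subgroup", "strand"]
print(result.truth[cols].head(8).round(1).to_string(index=False))
# Each row is one planted locus; true_age_my is the integration time the
# dating module should recover, and true_subgroup the LTR variant the
# phylogeny module should rediscover.
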