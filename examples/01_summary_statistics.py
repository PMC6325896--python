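"""Group summary statistics and per-individual heterozygosity.

Generates a small multi-group GBS-shaped dataset, then prints the
per-group statistics table (individuals per locus, variant /
polymorphic / private site counts, major-allele frequency, observed
heterozygosity, nucleotide diversity pi) and converts one group's pi
into an effective population size via pi = 4*Ne*mu.
"""

from gbspopgen import (
    generate, individual_heterozygosity, ne_from_pi, summary_table,
)

gm, pm, truth = generate("popstat-like", seed=42)
print(f"dataset: {gm.n_individuals} individuals x {gm.n_loci} SNPs, "
      f"{gm.total_sequence_length} bp surveyed\n")

table = summary_table(gm, pm)
print(table.round(4).to_string(index=False))
print()

# pi is per-bp diversity over the surveyed sequence (invariant sites
# included in the denominator); under neutrality pi = 4*Ne*mu links it
# to the effective population size at mu = 1e-9 /site/generation.
for _, row in table.iterrows():
    ne = ne_from_pi(row["pi"], mu=1e-9)
    print(f"{row['group']:>14}: pi = {row['pi']:.4f} -> Ne ~ {ne:,.0f}")

ind = gm.individuals[0]
h = individual_heterozygosity(gm, ind)
print(f"\nper-individual heterozygosity, e.g. {ind}: {h:.4f} per bp")
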