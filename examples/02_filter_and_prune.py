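"""Dataset-construction filtering and LD pruning.

Applies the two genotype-level dataset rules: keep loci genotyped in a
minimum fraction of individuals in a minimum number of populations
(Stacks -p/-r semantics), then remove one member of every SNP pair in
strong linkage disequilibrium (r2 > 0.2 within a 12.5 kb window).
"""

from gbspopgen import PruneConfig, filter_loci, generate, prune
from gbspopgen.ld import audit

gm, pm, _ = generate("hz2-like", seed=7, missingness=0.15)
print(f"input: {gm.n_loci} SNPs, 15% missing genotypes")

filtered = filter_loci(gm, pm, min_populations=3, min_fraction=0.70,
                       level="group")
print(f"after -p 3 -r 0.70 filter: {filtered.n_loci} SNPs")

cfg = PruneConfig(window_kb=12.5, step=5, r2_max=0.2, seed=1)
pruned = prune(filtered, cfg)
print(f"after LD pruning (r2 > {cfg.r2_max} within {cfg.window_kb} kb): "
      f"{pruned.n_loci} SNPs")

offenders = audit(pruned, cfg)
print(f"post-condition audit: {len(offenders)} surviving high-LD pairs "
      "(must be 0)")
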