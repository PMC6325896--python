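# gbspopgen

Population genetics for reduced-representation (GBS/RAD) SNP panels
from structured populations, with scenario-based demographic inference
by approximate Bayesian computation (ABC).

The package was built around a concrete biological question in the
Japanese medaka (*Oryzias latipes*) system: is a boundary-region group
(Tajima-Tango) a hybrid between the northern (N.JPN) and southern
(S.JPN) Japanese groups, or the source population the northern group
derives from — and when did the southern group disperse out of
northern Kyushu? Everything needed to ask such questions from diploid
biallelic SNP genotypes is included:

* **Genotype I/O and dataset construction** — VCF and population-map
  (individual → population → group) reading/writing; the
  locus-presence filter (`-p`/`-r` semantics: genotyped in ≥ r of
  individuals in ≥ p units) with exact-rational fraction comparison;
  windowed pairwise-r² LD pruning (12.5 kb / r² > 0.2 by default) with
  seeded random pair-member removal and an exhaustive post-condition
  audit.
* **Summary statistics** — per-group variant/polymorphic/private site
  counts, major-allele frequency, observed heterozygosity, and
  nucleotide diversity π = Σ (n/(n−1))(1−p²−q²) / L over the surveyed
  length; per-individual heterozygosity; Ne from π = 4·Ne·µ.
* **Fixed-allele-sharing classification** — each SNP where three
  groups are fixed two-vs-one is assigned to one of three sharing
  states, tabulated per chromosome.
* **Coalescent SNP simulation** — one segregating site per
  non-recombining locus under parameterized divergence/admixture
  scenarios (constant deme sizes), via a fast allele-count kernel for
  reference tables and msprime for full genotype matrices.
* **ABC engine** — the eight-statistic summary vector (gene diversity,
  Nei distance, admixture-estimate aggregates), reference tables,
  1 % rejection, weighted local linear regression adjustment with
  bound-respecting transforms, direct and logistic model choice, and
  RRMISE/RMeanAD/RRMSE accuracy metrics.
* **Synthetic data** — study-shaped datasets with known truth, so
  every stage is testable without any download.

## Worked example

Summary statistics on a synthetic multi-group panel
(`python examples/01_summary_statistics.py`):

```
       group  n_indiv_per_locus  ...  obs_het  se_obs_het     pi  se_pi
       N.JPN                6.0  ...   0.0644      0.0052 0.0035 0.0003
Tajima-Tango                5.0  ...   0.0693      0.0059 0.0036 0.0003
      Kyushu                3.0  ...   0.1017      0.0072 0.0055 0.0004
      Honshu                6.0  ...   0.1196      0.0067 0.0062 0.0003

         N.JPN: pi = 0.0035 -> Ne ~ 863,487
```

π is per-bp diversity over the surveyed sequence; the last line
converts it to an effective size at µ = 1e-9 /site/generation.

Dating a two-deme split by ABC
(`python examples/05_out_of_nk_dating.py`; truth is a 510 000
generation split baked into the synthetic dataset):

```
true split time: 510,000 generations
posterior mean : 546,847 (95% CI 289,449 - 821,544)
mean Ne from pi: 2,742,656 (pi = 0.0110, 0.0110; mu = 1e-09)
scaled by Ne   : 0.199 mean-Ne units
```

The posterior mean recovers the known truth within its credible
interval; the mean effective size derived from the observed π scales
the time axis for deme-sampled data (synthetic π is
ascertainment-inflated, so this Ne is demonstrative).

The other examples cover filtering/pruning, allele sharing, the
coalescent simulator, and four-scenario model choice. A thin CLI
exposes the same stages:

```sh
gbspopgen synth --template local-like --seed 1 --out data/
gbspopgen stats group --vcf data/genotypes.vcf --popmap data/popmap.tsv \
    --total-length 13262 --out summary.tsv
gbspopgen prune --vcf data/genotypes.vcf --seed 1 --out pruned.vcf
gbspopgen share --vcf hz.vcf --popmap hz.tsv \
    --groups N.JPN,Tajima-Tango,Honshu --out share.tsv
gbspopgen run-out-of-nk --template local-like --seed 1 --out run/
```

## Layout

```
src/gbspopgen/    genotypes, stats, ld, sharing, priors, scenarios,
                  simulate, abc, synth, workflows, cli
examples/         one short narrative script per capability
tests/            unit, property and acceptance suites
docs/methods.md   model, assumptions, parameters, limitations
```
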