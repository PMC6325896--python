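# Methods

`gbspopgen` implements a genotype-level population-genomics pipeline
for reduced-representation (GBS/RAD) SNP data from structured
populations — the setting of the Japanese medaka (*Oryzias latipes*)
system it was designed around, with a northern group (N.JPN), a
southern group split into Kyushu and Honshu components, a boundary
group (Tajima-Tango) of debated origin, and two wild-caught demes in
northern Kyushu (S.Saga, N.Saga). All components run end-to-end on
synthetic data with known truth.

## Genotype model and dataset construction

Genotypes are diploid biallelic alt-allele dosages (0/1/2, missing
allowed) over individuals × loci with chromosome/position metadata.
"Allele frequency" internally always means alt-allele frequency;
major/minor is derived at reporting time. An optional
`total_sequence_length` records the surveyed bp including invariant
sites — the denominator for per-bp nucleotide diversity.

Dataset construction mirrors the two genotype-level rules used to
build GBS SNP panels:

* **Locus presence filter** (`filter_loci`): keep loci genotyped in at
  least a fraction `r` of individuals in each of at least `p` units
  (populations by default, groups optionally — the statistics panel in
  the motivating study counts presence per group). The fraction test
  uses exact rationals (`calls/individuals >= decimal(r)`), so 14/20
  passes `r = 0.70` exactly, with no float rounding.
* **LD pruning** (`prune`): squared Pearson correlation of dosages
  over pairwise-complete individuals; one member of each
  same-chromosome pair within the 12.5 kb physical window with
  r² > 0.2 is removed, chosen uniformly at random under a mandatory
  seed (a minor-allele-frequency rule is selectable). The
  configuration keeps the conventional `(window_kb, step, r2)` triple,
  but the implementation enforces the post-condition over *every*
  in-window pair — the limit of the stepped slide — so the audit
  guarantee ("no surviving in-window pair with r² above threshold")
  holds unconditionally. Pairs with undefined r² (monomorphic on the
  complete set) cannot exceed the threshold and are skipped.

## Summary statistics

Per-group statistics follow the standard GBS reporting table: mean
individuals genotyped per locus, variant sites (variable over all
individuals jointly), polymorphic sites (variable within the group),
private alleles (an allele seen in this group and in no other), mean
major-allele frequency, mean observed heterozygosity, and nucleotide
diversity. Per-site diversity uses the unbiased gene-diversity form
`(n/(n-1)) (1 − p² − q²)` with `n` the called-allele count — equal to
the mean pairwise difference among sampled alleles — summed over
variant sites and divided by the total surveyed length. Reported
standard errors are across-site: for the per-site means σ/√sites, and
for π the standard error of the across-site sum propagated to per-bp
units. Missing data are ignored throughout (called alleles only). An
all-missing individual yields heterozygosity 0 with a warning rather
than an error so batch runs survive degenerate inputs.

`ne_from_pi` applies the neutral equilibrium relation π = 4 Ne µ with
µ defaulting to 1e-9 /site/generation and a 1-year generation, the
calibration appropriate for this system.

## Fixed-allele sharing

At a biallelic SNP where three groups are each fixed (within-group
frequency exactly 0 or 1 over called alleles, requiring ≥ 2 called
alleles per group by default), two groups share one allele and the
third carries the other; sites where all three agree are invariant in
the trio and not counted. The per-chromosome tabulation of the three
states measures which pair of groups is genomically closest. A
relaxed mode (fixation at ≤ δ / ≥ 1−δ) exists but is off by default;
strict fixation is the definition used for reported proportions.

## Coalescent SNP simulation

Each locus is an independent non-recombining genealogy under a
structured coalescent with constant diploid deme sizes and two event
types (backward in time): merges (all lineages of one deme move to
another) and admixture (each lineage moves to parent 1 with
probability r, else parent 2). Exactly one mutation is placed on a
branch chosen proportionally to branch length, so every locus is
polymorphic in the pooled sample — the ascertainment regime of
SNP-mode ABC simulators and of GBS SNP panels. No mutation rate enters
the simulation; times and sizes are jointly identified and reported in
natural units (generations = years), with optional scaling by a mean
effective size at the reporting layer.

Two conditioning modes are provided. `"genealogy"` (default) keeps
every genealogy and is the fixed-one-mutation scheme of the classic
SNP simulators; it is used consistently for reference tables and
synthetic observed data, so ABC compares like with like. `"site"`
additionally weights genealogies by total branch length (rejection
against an empirically set bound of twice the largest pre-pass
length; the rare longer genealogy is kept, a negligible and
documented truncation), which is the low-mutation-rate limit of
conditioning on one segregating site. The distinction matters for the
site-frequency spectrum: only the site-conditioned mode yields the
exact neutral `P(i) ∝ 1/i` law, because `E[L_i/L] ≠ E[L_i]/E[L]`
under unweighted genealogies. The test suite checks the spectrum in
site mode and the TMRCA law (`E[TMRCA] = 3N` for four lineages) in
the unconditioned mode.

Two engines implement the same model: a numba kernel returning
per-deme derived-allele counts (≈ 10 µs per genealogy; used for
reference tables, where millions of genealogies are needed) and an
msprime-based engine returning full diploid genotype matrices (used
for synthetic datasets). A distribution-level test asserts their
summary-statistic means agree; the msprime route doubles as an
independent oracle for the kernel. The kernel supports up to 64
sampled alleles (lineage sets are bitmasks).

## Scenario templates

Four templates describe the boundary group's origin; all share a root
split of a northern and a southern lineage from one ancestor at t3,
with the Kyushu–Honshu divergence at t2 and the boundary-group event
at t1 (t3 > t2, t3 > t1, t2 ≥ t1):

* **I** — Tajima-Tango is a recent offshoot of N.JPN (backward: TT
  merges into N.JPN at t1); Honshu carries the southern lineage.
* **II** — Tajima-Tango formed by admixture between N.JPN (fraction
  r) and Honshu at t1; Honshu carries the southern lineage.
* **III** — N.JPN originated in Tajima-Tango (N.JPN merges into TT at
  t1); Kyushu carries the southern lineage.
* **IV** — the admixture origin of II combined with the
  Kyushu-ancestral southern topology of III.

The two admixture templates necessarily share their admixture parents
(the parameter tables of the motivating analysis give scenario IV no
separate N.JPN–Tajima-Tango divergence time), so the pairs I/II and
III/IV are distinguished by which southern deme is ancestral — the
reading under which all four topologies are distinct and every prior
parameter maps onto one template slot. A fifth two-deme template
(N.Saga diverging from S.Saga at t) supports the split-dating
workflow.

Priors are the study's: truncated normals on deme sizes (e.g.
N(450 000, 500 000) on [10⁴, 3×10⁶] for N.JPN), uniform divergence
times on [10, 4×10⁶], a truncated normal N(4×10⁶, 5×10⁶) on
[10⁶, 3×10⁷] for the deep north–south split, and Uniform(0.001,
0.999) for the admixture rate. Truncation is by rejection (no mass
piled at the bounds); joint draws violating the time ordering are
redrawn, with an error after 10 000 consecutive rejections.

## ABC engine

The summary-statistic vector concatenates, per declared layout:
per group the proportion of loci with null gene diversity and the
mean gene diversity across polymorphic loci; per pair the proportion
of null Nei standard distances and the variance of non-null
distances; per (admixed, parent1, parent2) trio the proportion of
null admixture estimates `(p_adm − p2)/(p1 − p2)`, their non-null
mean and variance, and the mean across all defined loci. "Null"
means exactly zero. Undefined admixture estimates (equal parental
frequencies, tolerance 1e-12) are excluded from every aggregate;
infinite Nei distances (fixed opposite alleles) are capped at 10.
Loci where an ingredient group has fewer than two called alleles are
excluded from that statistic. Statistics are standardized by their
standard deviation across the reference table (constant statistics
get unit sd and contribute nothing to distances).

Estimation is rejection plus weighted local linear regression: accept
the ⌈tolerance·N⌉ closest records by Euclidean distance on
standardized vectors; weight them with an Epanechnikov kernel whose
bandwidth is the largest accepted distance; map each parameter to an
unbounded scale (logit on its prior bounds, identity when unbounded);
regress on the centered standardized statistics by weighted least
squares; subtract the fitted statistic effect. The logit transform
keeps adjusted draws inside the prior support by construction. Point
estimates are the weighted mean, median and KDE mode with weighted
2.5/97.5 % quantiles. A singular design falls back to the unadjusted
rejection sample with a warning.

Model choice offers both standard methods: the **direct** estimate
(scenario share among the n closest records, default 500, with a
normal-approximation binomial interval) and **multinomial logistic
regression** of the scenario label on standardized statistics over
the accepted set, evaluated at the observed vector, with delta-method
intervals from the fitted covariance; a perfectly separated accepted
set returns the degenerate answer directly, and other fit failures
fall back to a regularized fit with binomial-style intervals and a
warning.

Accuracy metrics follow the relative-error conventions of
scenario-based ABC software: with test truths θ_j and posterior draws
θ*_jk (weights normalized per test set),
RRMISE = √(mean_j mean_k ((θ*_jk − θ_j)/θ_j)²),
RMeanAD = mean_j mean_k |θ*_jk − θ_j|/θ_j, and
RRMSE = √(mean_j ((θ̂_j − θ_j)/θ_j)²) with θ̂_j the weighted posterior
mean. Test truths come from the prior and, optionally, from a
supplied posterior sample ("posterior (prior)" paired reporting);
zero-valued truths are excluded from relative metrics with a warning
counter. These formulas are this package's contract — the upstream
tool does not document its exact forms.

`scale_parameters` converts every parameter between natural units and
mean-Ne units (divide/multiply); the round trip is the identity. The
two-deme workflow derives the mean Ne from the observed per-deme π
via π = 4 Ne µ and reports it with its inputs.

## Synthetic data

Templates mirror the study shapes: `hz2-like` (4 groups × 5
single-individual populations, 1 014 SNPs, generated under scenario
III), `local-like` (2 demes × 6 diploids, 698 SNPs, split at 510 000
generations), `popstat-like` (a smaller multi-group statistics
panel). True parameters default to the demographic point estimates
this kind of analysis reports on such data, so recovery experiments
operate in a realistic parameter regime; truth records carry scenario,
parameters and seed, and recovery suites read truth only from them.
Loci are spread over 24 chromosomes at 100 kb spacing (no background
LD between independent loci), and `total_sequence_length` is set at
19 bp of surveyed sequence per retained SNP, the ratio typical of
these panels. Missingness is uniform at random by default — real GBS
missingness is locus-structured, so a per-locus beta-dropout mode is
provided — and synthetic π is ascertainment-inflated relative to real
per-bp diversity (every simulated locus is a SNP), which matters only
where a workflow derives Ne from synthetic π, never for recovery of
times/sizes.

What passing on synthetic data does not show: robustness to
locus-structured missingness and genotyping error, to within-locus
recombination or background LD, to non-equilibrium size change
(growth/bottlenecks are outside the scenario space by design), or to
the deme-vs-lab-stock sampling mismatch that motivates scaled
reporting on real data.

## Problem sizes and numerical choices

Default workflow sizes (10 000 simulations per scenario, ~1 000 loci,
1 % tolerance) were chosen so a full run completes in minutes on one
CPU; they are ordinary configuration values, and the stochastic test
suite uses the same sizes it states in each test. The recovery suite
draws each replicate's truth from the prior, which makes 95 %
credible-interval coverage self-calibrating; its reference table is
built once and shared across replicates. Determinism: every stochastic
entry point takes a seed; kernel seeds are reduced mod 2³¹−1; reports
contain no timestamps and hash their configuration (minus output
paths).

Known limitations: the kernel's 64-allele cap; the admixture-statistic
trio must be declared in the layout (which trios enter for
non-admixture scenarios is a user choice, defaulting to the boundary
trio); Nei-distance capping makes the pair variance scale-dependent in
the rare fixed-opposite case; the logistic fallback's intervals are
binomial-style rather than delta-method; local-linear adjustment can
be anti-conservative when the accepted count is small relative to the
statistic dimension (the suite's sizes keep that ratio ≥ 20).
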