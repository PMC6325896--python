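"""Coalescent simulation of SNP loci under demographic scenarios.

Each locus is an independent non-recombining genealogy of all sampled
lineages under the scenario's structured coalescent (times in
generations, constant diploid deme sizes).  Exactly one mutation is
placed on a branch chosen with probability proportional to branch
length, so every locus is polymorphic in the pooled sample -- the
SNP-ascertained regime of GBS data and of SNP-mode ABC simulators.
Because of this conditioning no mutation rate enters the simulation;
times and sizes are identifiable jointly.

Two engines are provided:

* a purpose-built numba kernel (:func:`simulate_counts`) returning only
  per-deme derived-allele counts -- fast enough for ABC reference tables
  with millions of genealogies;
* an msprime-based engine (:func:`simulate_snps`) returning full diploid
  genotype matrices for synthetic datasets, which also serves as an
  independent cross-check of the kernel in the test suite.

Both are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeMatrix
from .scenarios import DemographicScenario


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        x &= x - np.uint64(1)
        c += 1
    return c


@njit(cache=True)
def _sim_loci(seed, n_loci, lin_pop0, n_demes, sizes,
              ev_t, ev_ty, ev_a, ev_b, ev_c, ev_p,
              counts, tmrca, lengths, length_bound):
    """Structured-coalescent kernel; one mutation per genealogy.

    Fills ``counts`` (n_loci x n_demes derived-allele counts among the
    sampled alleles, demes in initial-deme order) and ``tmrca``.

    ``length_bound`` <= 0 keeps every genealogy (fixed one-mutation
    conditioning); a positive value enables length-biased rejection
    (accept a genealogy with probability total_length / length_bound),
    the low-mutation-rate limit of conditioning on one segregating
    site.
    """
    np.random.seed(seed)
    n_lin0 = lin_pop0.size
    n_ev = ev_t.size
    one = np.uint64(1)

    # per-deme masks of the initial sample
    deme_mask = np.zeros(n_demes, dtype=np.uint64)
    for i in range(n_lin0):
        deme_mask[lin_pop0[i]] |= one << np.uint64(i)

    mask = np.empty(n_lin0, dtype=np.uint64)
    birth = np.empty(n_lin0, dtype=np.float64)
    k_in = np.empty(n_demes, dtype=np.int64)
    rate = np.empty(n_demes, dtype=np.float64)
    # per-deme membership lists: members[d, :k_in[d]] are alive lineages
    members = np.empty((n_demes, n_lin0), dtype=np.int64)
    scratch = np.empty(n_lin0, dtype=np.int64)

    for loc in range(n_loci):
      while True:  # length-biased rejection loop (single pass if off)
        for d in range(n_demes):
            k_in[d] = 0
        for i in range(n_lin0):
            mask[i] = one << np.uint64(i)
            birth[i] = 0.0
            d = lin_pop0[i]
            members[d, k_in[d]] = i
            k_in[d] += 1
        active = n_lin0
        t = 0.0
        ev_i = 0
        total_len = 0.0
        chosen = np.uint64(0)

        R = 0.0
        for d in range(n_demes):
            rate[d] = k_in[d] * (k_in[d] - 1) / (4.0 * sizes[d])
            R += rate[d]

        while active > 1:
            if R > 0.0:
                t_cand = t + np.random.exponential(1.0 / R)
            else:
                t_cand = np.inf
            if ev_i < n_ev and ev_t[ev_i] < t_cand:
                # apply demographic event
                t = ev_t[ev_i]
                src = ev_a[ev_i]
                n_move = k_in[src]
                for s in range(n_move):
                    scratch[s] = members[src, s]
                k_in[src] = 0
                if ev_ty[ev_i] == 0:
                    dst = ev_b[ev_i]
                    for s in range(n_move):
                        members[dst, k_in[dst]] = scratch[s]
                        k_in[dst] += 1
                else:
                    d1 = ev_b[ev_i]
                    d2 = ev_c[ev_i]
                    pr = ev_p[ev_i]
                    for s in range(n_move):
                        dst = d1 if np.random.random() < pr else d2
                        members[dst, k_in[dst]] = scratch[s]
                        k_in[dst] += 1
                R = 0.0
                for d in range(n_demes):
                    rate[d] = k_in[d] * (k_in[d] - 1) / (4.0 * sizes[d])
                    R += rate[d]
                ev_i += 1
                continue
            # coalescence at t_cand
            t = t_cand
            u = np.random.random() * R
            d = 0
            acc = rate[0]
            while acc < u and d < n_demes - 1:
                d += 1
                acc += rate[d]
            # pick two distinct lineages in deme d
            r1 = np.random.randint(0, k_in[d])
            r2 = np.random.randint(0, k_in[d] - 1)
            if r2 >= r1:
                r2 += 1
            i1 = members[d, r1]
            i2 = members[d, r2]
            # close both child edges; weighted-reservoir mutation pick
            L1 = t - birth[i1]
            total_len += L1
            if L1 > 0.0 and np.random.random() < L1 / total_len:
                chosen = mask[i1]
            L2 = t - birth[i2]
            total_len += L2
            if L2 > 0.0 and np.random.random() < L2 / total_len:
                chosen = mask[i2]
            # merge i2 into i1; drop i2 from the deme list
            mask[i1] |= mask[i2]
            birth[i1] = t
            lastslot = k_in[d] - 1
            members[d, r2] = members[d, lastslot]
            k_in[d] = lastslot
            active -= 1
            R -= rate[d]
            rate[d] = k_in[d] * (k_in[d] - 1) / (4.0 * sizes[d])
            R += rate[d]

        if length_bound > 0.0 and (
                np.random.random() * length_bound >= total_len):
            continue  # reject; resimulate this locus
        tmrca[loc] = t
        lengths[loc] = total_len
        for d in range(n_demes):
            counts[loc, d] = _popcount(chosen & deme_mask[d])
        break


def simulate_counts(sc: DemographicScenario, draw: dict[str, float],
                    n_loci: int, sample_sizes: dict[str, int], seed: int,
                    *, conditioning: str = "genealogy"):
    """Simulate derived-allele counts per sampled deme.

    Parameters
    ----------
    sample_sizes
        Diploids per sampled deme (deme name -> count); total sampled
        alleles must be <= 64.
    seed
        Seed for the kernel RNG (int, < 2**31).
    conditioning
        ``"genealogy"`` (default): exactly one mutation on every
        genealogy -- the SNP scheme of DIYABC-style simulators.
        ``"site"``: genealogies additionally weighted by total branch
        length (rejection), the low-mutation-rate limit of
        conditioning on one segregating site; this mode yields the
        exact 1/i neutral frequency spectrum.

    Returns
    -------
    counts : (n_loci, n_demes) int array of derived-allele counts
    n_alleles : (n_demes,) int array of sampled alleles per deme
    tmrca : (n_loci,) float array of pooled-sample TMRCAs (generations)
    """
    if conditioning not in ("genealogy", "site"):
        raise ValueError("conditioning must be 'genealogy' or 'site'")
    demes = sc.populations
    n_hap = [2 * sample_sizes.get(d, 0) for d in demes]
    total = sum(n_hap)
    if total == 0:
        raise ValueError("zero sampled lineages")
    if total > 64:
        raise ValueError("kernel supports at most 64 sampled alleles")
    lin_pop0 = np.repeat(
        np.arange(len(demes), dtype=np.int64), n_hap
    )
    sizes = sc.sizes(draw)
    t, ty, a, b, c, p = sc.event_arrays(draw)
    n_all_demes = len(sc.all_demes)
    seed = int(seed) % (2**31 - 1)
    bound = 0.0
    if conditioning == "site":
        # empirical bound for the acceptance ratio: overshoot the
        # largest total length seen in an unweighted pre-pass
        # (genealogies rarely exceeding it are simply kept)
        pre_counts = np.zeros((200, n_all_demes), dtype=np.int64)
        pre_tm = np.zeros(200)
        pre_len = np.zeros(200)
        _sim_loci((seed + 1) % (2**31 - 1), 200, lin_pop0, n_all_demes,
                  sizes, t, ty, a, b, c, p, pre_counts, pre_tm, pre_len,
                  0.0)
        bound = 2.0 * float(pre_len.max())
    counts = np.zeros((n_loci, n_all_demes), dtype=np.int64)
    tmrca = np.zeros(n_loci)
    lengths = np.zeros(n_loci)
    _sim_loci(seed, n_loci, lin_pop0, n_all_demes, sizes,
              t, ty, a, b, c, p, counts, tmrca, lengths, bound)
    return counts[:, : len(demes)], np.array(n_hap), tmrca


def assign_positions(n_loci: int, n_chromosomes: int = 24,
                     spacing: int = 100_000) -> pd.DataFrame:
    """Spread loci over chromosomes in contiguous equal blocks."""
    per = int(np.ceil(n_loci / n_chromosomes))
    chrom = [f"chr{1 + i // per}" for i in range(n_loci)]
    pos = [spacing * (1 + i % per) for i in range(n_loci)]
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"}
    )


def simulate_snps(sc: DemographicScenario, draw: dict[str, float],
                  n_loci: int, sample_sizes: dict[str, int], seed: int,
                  *, individual_names: list[str] | None = None,
                  n_chromosomes: int = 24, spacing: int = 100_000,
                  total_sequence_length: int | None = None,
                  conditioning: str = "genealogy") -> GenotypeMatrix:
    """Simulate a diploid genotype matrix with msprime genealogies.

    One mutation per locus is placed on a branch drawn proportionally to
    branch length; the derived allele is the alt allele.  Diploids are
    formed by msprime's individual pairing of haploid lineages.  See
    :func:`simulate_counts` for the ``conditioning`` modes.
    """
    import msprime

    if conditioning not in ("genealogy", "site"):
        raise ValueError("conditioning must be 'genealogy' or 'site'")
    demes = [d for d in sc.populations if sample_sizes.get(d, 0) > 0]
    if not demes:
        raise ValueError("zero sampled lineages")
    dem = sc.to_msprime(draw)
    samples = [
        msprime.SampleSet(sample_sizes[d], population=sc.msprime_name(d),
                          ploidy=2)
        for d in demes
    ]
    rng = np.random.default_rng(seed)
    n_ind = sum(sample_sizes[d] for d in demes)
    calls = np.zeros((n_ind, n_loci), dtype=np.int8)

    def replicates(n, sub_seed):
        return msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=2,
            num_replicates=n, random_seed=sub_seed % (2**31 - 2) + 1,
        )

    bound = None
    if conditioning == "site":
        pre = [ts.first().total_branch_length
               for ts in replicates(100, seed + 7)]
        bound = 2.0 * max(pre)

    loc = 0
    batch = 0
    while loc < n_loci:
        need = n_loci - loc
        for ts in replicates(need, seed + 1000 * batch):
            tree = ts.first()
            if tree.num_roots != 1:
                raise RuntimeError("genealogy did not fully coalesce")
            if bound is not None and (
                    rng.random() * bound >= tree.total_branch_length):
                continue
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lengths = np.array([tree.branch_length(u) for u in nodes])
            u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
            for node in tree.samples(u):
                ind = ts.node(node).individual
                calls[ind, loc] += 1
            loc += 1
        batch += 1
    if individual_names is None:
        individual_names = []
        for d in demes:
            individual_names += [
                f"{d}-{k + 1}" for k in range(sample_sizes[d])
            ]
    loci = assign_positions(n_loci, n_chromosomes, spacing)
    return GenotypeMatrix(
        individuals=individual_names, loci=loci, calls=calls,
        total_sequence_length=total_sequence_length,
    )


def counts_from_matrix(gm: GenotypeMatrix, pm, groups: list[str]):
    """Per-group (derived count, called alleles) arrays from genotypes."""
    from .stats import _group_counts

    L = gm.n_loci
    counts = np.zeros((L, len(groups)))
    n_all = np.zeros((L, len(groups)))
    for k, g in enumerate(groups):
        idx = pm.indices(gm, group=g)
        alt, n, _ = _group_counts(gm, idx)
        counts[:, k] = alt
        n_all[:, k] = n
    return counts, n_all
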