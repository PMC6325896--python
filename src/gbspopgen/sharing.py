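"""Fixed-allele-sharing classification among three groups.

At a biallelic SNP where each of three groups is fixed (within-group
alt-allele frequency exactly 0 or 1 over called alleles), two groups
share one allele and the third carries the other.  Each such site falls
into one of three states -- shared(A,B), shared(A,C), shared(B,C) -- and
the per-chromosome tabulation of the states summarizes which pair of
groups is genetically closest across the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError, PopulationMap
from .stats import _group_counts


@dataclass
class SharingTable:
    groups: tuple[str, str, str]
    per_chromosome: pd.DataFrame  # chrom x 3 state columns
    totals: dict[str, int]
    proportions: dict[str, float]
    n_classified: int
    n_input_snps: int
    no_classified_sites: bool = False

    def state_names(self) -> list[str]:
        a, b, c = self.groups
        return [f"shared({a},{b})", f"shared({a},{c})", f"shared({b},{c})"]


_PAIRS = ((0, 1), (0, 2), (1, 2))


def classify_site(freq_a: float | None, freq_b: float | None,
                  freq_c: float | None) -> int | None:
    """Classify one site into a sharing state.

    Returns the index of the fixed-sharing pair in the order
    ``(A,B), (A,C), (B,C)``, or ``None`` when any group is unfixed or
    undefined, or when all three groups agree (invariant trio).
    """
    freqs = (freq_a, freq_b, freq_c)
    if any(f is None or np.isnan(f) for f in freqs):
        return None
    fixed = [f in (0.0, 1.0) for f in freqs]
    if not all(fixed):
        return None
    if freqs[0] == freqs[1] == freqs[2]:
        return None
    for k, (i, j) in enumerate(_PAIRS):
        other = 3 - i - j
        if freqs[i] == freqs[j] != freqs[other]:
            return k
    return None  # unreachable for biallelic fixed trios


def sharing_table(gm: GenotypeMatrix, pm: PopulationMap,
                  groups: tuple[str, str, str], *,
                  min_alleles: int = 2,
                  fixation_delta: float = 0.0) -> SharingTable:
    """Tabulate fixed-allele sharing states per chromosome.

    ``min_alleles`` is the minimum called-allele count a group needs at
    a site for its frequency to count (default 2).  ``fixation_delta``
    optionally relaxes "fixed" to frequency <= delta or >= 1-delta;
    the default 0.0 is strict fixation.
    """
    pm.check_covers(gm)
    if len(groups) != 3 or len(set(groups)) != 3:
        raise GenotypeError("exactly three distinct groups required")
    for g in groups:
        if g not in pm.groups:
            raise GenotypeError(f"group {g!r} absent from population map")

    freqs = np.full((3, gm.n_loci), np.nan)
    for k, g in enumerate(groups):
        idx = pm.indices(gm, group=g)
        alt, n, _ = _group_counts(gm, idx)
        ok = n >= min_alleles
        freqs[k, ok] = alt[ok] / n[ok]

    if fixation_delta > 0:
        # snap nearly-fixed frequencies to 0/1 in relaxed mode
        freqs = np.where(freqs <= fixation_delta, 0.0, freqs)
        freqs = np.where(freqs >= 1.0 - fixation_delta, 1.0, freqs)

    states = np.full(gm.n_loci, -1, dtype=int)
    for j in range(gm.n_loci):
        s = classify_site(freqs[0, j], freqs[1, j], freqs[2, j])
        if s is not None:
            states[j] = s

    chroms = gm.loci["chrom"]
    cols = [f"state{k}" for k in range(3)]
    rows = []
    for chrom in dict.fromkeys(chroms):
        sel = (chroms == chrom).to_numpy()
        rows.append(
            [chrom] + [int(((states == k) & sel).sum()) for k in range(3)]
        )
    per_chrom = pd.DataFrame(rows, columns=["chrom"] + cols).set_index("chrom")

    a, b, c = groups
    names = [f"shared({a},{b})", f"shared({a},{c})", f"shared({b},{c})"]
    totals = {names[k]: int((states == k).sum()) for k in range(3)}
    n_classified = sum(totals.values())
    if n_classified:
        proportions = {k: v / n_classified for k, v in totals.items()}
        flag = False
    else:
        proportions = {k: 0.0 for k in totals}
        flag = True
    per_chrom.columns = names
    return SharingTable(
        groups=tuple(groups),
        per_chromosome=per_chrom,
        totals=totals,
        proportions=proportions,
        n_classified=n_classified,
        n_input_snps=gm.n_loci,
        no_classified_sites=flag,
    )
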