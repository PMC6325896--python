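"""Group summary statistics, per-individual heterozygosity, and the
pi = 4*Ne*mu effective-size conversion.

The group summary mirrors the usual GBS reporting table: mean number of
individuals genotyped per locus, variant sites (variable over all groups
jointly), polymorphic sites (variable within the group), private alleles
(seen in this group and no other), mean major-allele frequency, mean
observed heterozygosity, and per-bp nucleotide diversity pi.

Per-site diversity uses the unbiased gene-diversity form
``(n/(n-1)) * (1 - p^2 - q^2)`` with ``n`` the number of called alleles,
which equals the mean pairwise difference among the ``n`` sampled
alleles.  pi divides the sum over variant sites by the total surveyed
sequence length (invariant sites included in the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError, PopulationMap


@dataclass
class GroupSummary:
    group: str
    mean_individuals_per_locus: float
    se_individuals: float
    total_length: int | None
    n_variant_sites: int
    n_polymorphic: int
    n_private: int
    major_allele_freq: float
    se_major_allele_freq: float
    observed_heterozygosity: float
    se_observed_heterozygosity: float
    nucleotide_diversity: float | None
    se_nucleotide_diversity: float | None

    def as_row(self) -> dict:
        return {
            "group": self.group,
            "n_indiv_per_locus": self.mean_individuals_per_locus,
            "total_length_bp": self.total_length,
            "variant": self.n_variant_sites,
            "polymorphic": self.n_polymorphic,
            "private": self.n_private,
            "major_allele_freq": self.major_allele_freq,
            "se_maf": self.se_major_allele_freq,
            "obs_het": self.observed_heterozygosity,
            "se_obs_het": self.se_observed_heterozygosity,
            "pi": self.nucleotide_diversity,
            "se_pi": self.se_nucleotide_diversity,
        }


@dataclass
class EffectiveSize:
    ne: float
    mu: float
    generation_years: float = 1.0

    def __post_init__(self) -> None:
        if self.ne < 0 or self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("Ne >= 0, mu > 0, generation_years > 0 required")


def _group_counts(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-locus (alt-allele count, called-allele count, het count)."""
    calls = gm.calls[idx, :]
    called = calls >= 0
    alt = np.where(called, calls, 0).sum(axis=0).astype(float)
    n = 2.0 * called.sum(axis=0)
    het = (calls == 1).sum(axis=0).astype(float)
    return alt, n, het


def group_allele_freq(gm: GenotypeMatrix, pm: PopulationMap, group: str,
                      locus: int | None = None):
    """Alt-allele frequency within a group: dosage sum / (2 x called).

    With ``locus=None`` returns the full per-locus array (NaN where the
    group has no calls); with an index returns a scalar or ``None``.
    """
    idx = pm.indices(gm, group=group)
    alt, n, _ = _group_counts(gm, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.where(n > 0, n, 1), np.nan)
    if locus is None:
        return freq
    f = freq[locus]
    return None if np.isnan(f) else float(f)


def _se(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def group_summary(gm: GenotypeMatrix, pm: PopulationMap,
                  group: str) -> GroupSummary:
    """Summary genetic statistics for one group.

    Variant sites are counted jointly over all individuals in the
    matrix; polymorphic and private counts, frequencies, heterozygosity
    and pi are computed within the group on called alleles only.
    """
    pm.check_covers(gm)
    idx = pm.indices(gm, group=group)

    all_idx = np.arange(gm.n_individuals)
    alt_all, n_all, _ = _group_counts(gm, all_idx)
    # variable over all groups jointly: both alleles seen somewhere
    variant = (alt_all > 0) & (alt_all < n_all)
    n_variant = int(variant.sum())

    alt_g, n_g, het_g = _group_counts(gm, idx)
    poly = variant & (alt_g > 0) & (alt_g < n_g)
    n_poly = int(poly.sum())

    # private alleles: an allele present in this group and absent from
    # every other group (alt side or ref side), at variant sites
    others = np.setdiff1d(all_idx, idx)
    alt_o, n_o, _ = _group_counts(gm, others)
    ref_g = n_g - alt_g
    ref_o = n_o - alt_o
    private = variant & (
        ((alt_g > 0) & (alt_o == 0)) | ((ref_g > 0) & (ref_o == 0))
    )
    n_private = int(private.sum())

    informative = variant & (n_g > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_g > 0, alt_g / np.where(n_g > 0, n_g, 1), np.nan)
    maf = np.maximum(p, 1 - p)[informative]
    het_rate = (het_g / (n_g / 2.0))[informative]

    pi = se_pi = None
    if gm.total_sequence_length is not None:
        unbiased = variant & (n_g >= 2)
        n_u = n_g[unbiased]
        p_u = alt_g[unbiased] / n_u
        d = (n_u / (n_u - 1.0)) * (1.0 - p_u**2 - (1.0 - p_u) ** 2)
        L = gm.total_sequence_length
        pi = float(d.sum() / L)
        # SE of a sum of independent per-site terms, per bp
        se_pi = (
            float(d.std(ddof=1) * np.sqrt(len(d)) / L) if len(d) > 1 else 0.0
        )

    n_per_locus = n_g / 2.0
    return GroupSummary(
        group=group,
        mean_individuals_per_locus=float(np.mean(n_per_locus)),
        se_individuals=_se(n_per_locus),
        total_length=gm.total_sequence_length,
        n_variant_sites=n_variant,
        n_polymorphic=n_poly,
        n_private=n_private,
        major_allele_freq=float(np.mean(maf)) if len(maf) else float("nan"),
        se_major_allele_freq=_se(maf),
        observed_heterozygosity=(
            float(np.mean(het_rate)) if len(het_rate) else float("nan")
        ),
        se_observed_heterozygosity=_se(het_rate),
        nucleotide_diversity=pi,
        se_nucleotide_diversity=se_pi,
    )


def summary_table(gm: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Group summaries for every group in the map, as one DataFrame."""
    return pd.DataFrame(
        [group_summary(gm, pm, g).as_row() for g in pm.groups]
    )


def individual_heterozygosity(gm: GenotypeMatrix, individual: str) -> float:
    """Per-bp heterozygosity of one individual: het sites / total length.

    An all-missing individual yields 0.0 with a warning rather than an
    error, so batch runs survive degenerate inputs.
    """
    if gm.total_sequence_length is None:
        raise GenotypeError("total_sequence_length required")
    i = gm.individual_index(individual)
    row = gm.calls[i, :]
    if not (row >= 0).any():
        warnings.warn(
            f"individual {individual!r} has no called genotypes",
            stacklevel=2,
        )
        return 0.0
    return float((row == 1).sum() / gm.total_sequence_length)


def individual_heterozygosity_table(gm: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": gm.individuals,
            "heterozygosity": [
                individual_heterozygosity(gm, ind) for ind in gm.individuals
            ],
        }
    )


def ne_from_pi(pi: float, mu: float = 1e-9) -> float:
    """Effective population size from pi = 4*Ne*mu (infinite sites,
    constant-size Wright-Fisher)."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return pi / (4.0 * mu)
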