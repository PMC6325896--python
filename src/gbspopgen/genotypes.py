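"""Genotype matrices, population maps, and dataset-construction filters.

The central container is :class:`GenotypeMatrix`: diploid biallelic
alt-allele dosages (0/1/2, ``-1`` for missing) over individuals x loci,
with chromosome/position metadata and an optional total surveyed sequence
length (the denominator for per-bp nucleotide diversity, which must count
invariant sites).  :class:`PopulationMap` assigns each individual to a
population nested inside a group.

Dosages are always counted on the alt allele; "allele frequency" in this
package means alt-allele frequency unless a function says otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised for malformed genotype data or violated preconditions."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP dosages over individuals x loci.

    Parameters
    ----------
    individuals
        Ordered unique individual identifiers.
    loci
        DataFrame with columns ``chrom, pos, ref, alt``; positions are
        1-based and strictly increasing within a chromosome.
    calls
        ``(n_individuals, n_loci)`` int8 array of alt-allele dosages in
        {0, 1, 2} with -1 for missing.
    total_sequence_length
        Optional bp of surveyed sequence including invariant sites.
    """

    individuals: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    total_sequence_length: int | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeError("duplicate individual identifiers")
        if list(self.loci.columns[:4]) != LOCUS_COLUMNS:
            raise GenotypeError(f"loci must have columns {LOCUS_COLUMNS}")
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.loci)})"
            )
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise GenotypeError("dosage values must be in {0,1,2,-1}")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on {chrom}"
                )
        ids = list(zip(self.loci["chrom"], self.loci["pos"]))
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate locus identifiers")

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def individual_index(self, name: str) -> int:
        try:
            return self.individuals.index(name)
        except ValueError:
            raise GenotypeError(f"unknown individual {name!r}") from None

    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        """Return a copy restricted to the given loci (order preserved)."""
        idx = np.arange(self.n_loci)[mask_or_index]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
            total_sequence_length=self.total_sequence_length,
        )

    def subset_individuals(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(n) for n in names]
        return GenotypeMatrix(
            individuals=list(names),
            loci=self.loci.copy(),
            calls=self.calls[idx, :].copy(),
            total_sequence_length=self.total_sequence_length,
        )

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls >= 0

    def equal(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
            and self.loci[LOCUS_COLUMNS].equals(other.loci[LOCUS_COLUMNS])
        )


@dataclass
class PopulationMap:
    """individual -> (population, group) assignments.

    Every individual appears once; every population belongs to exactly
    one group.
    """

    table: pd.DataFrame  # columns: individual, population, group

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:3]) != ["individual", "population", "group"]:
            raise GenotypeError(
                "population map needs columns individual, population, group"
            )
        if t["individual"].duplicated().any():
            dups = t.loc[t["individual"].duplicated(), "individual"].tolist()
            raise GenotypeError(f"duplicate individuals in map: {dups}")
        pg = t.drop_duplicates(["population", "group"])
        if pg["population"].duplicated().any():
            bad = pg.loc[pg["population"].duplicated(), "population"].tolist()
            raise GenotypeError(f"population mapped to two groups: {bad}")
        if len(t) == 0:
            raise GenotypeError("empty population map")
        self.table = t.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return self.table["individual"].tolist()

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def individuals_in(self, *, population: str | None = None,
                       group: str | None = None) -> list[str]:
        t = self.table
        if population is not None:
            t = t[t["population"] == population]
        if group is not None:
            t = t[t["group"] == group]
        return t["individual"].tolist()

    def group_of(self, individual: str) -> str:
        row = self.table[self.table["individual"] == individual]
        if row.empty:
            raise GenotypeError(f"unknown individual {individual!r}")
        return row["group"].iloc[0]

    def indices(self, gm: GenotypeMatrix, *, population: str | None = None,
                group: str | None = None) -> np.ndarray:
        """Row indices into ``gm.calls`` for the selected unit."""
        names = self.individuals_in(population=population, group=group)
        if group is not None and not names:
            raise GenotypeError(f"unknown group {group!r}")
        return np.array([gm.individual_index(n) for n in names], dtype=int)

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = set(gm.individuals) - set(self.individuals)
        if missing:
            raise GenotypeError(
                f"individuals absent from population map: {sorted(missing)}"
            )


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, *, strict_biallelic: bool = True,
             total_sequence_length: int | None = None) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records raise :class:`GenotypeError` in strict mode
    (the default) and are dropped otherwise.  Missing genotypes (``./.``)
    become missing dosages.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeError(f"cannot parse VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if strict_biallelic:
                raise GenotypeError(
                    f"non-biallelic record {var.CHROM}:{var.POS} "
                    f"(ALT={var.ALT})"
                )
            continue
        dosages = np.empty(len(individuals), dtype=np.int8)
        for k, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise GenotypeError(
                    f"non-diploid GT at {var.CHROM}:{var.POS} sample "
                    f"{individuals[k]}"
                )
            a, b = alleles
            dosages[k] = MISSING if (a < 0 or b < 0) else np.int8(a + b)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dosages)
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    calls = (
        np.stack(rows, axis=1)
        if rows else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, calls,
                          total_sequence_length=total_sequence_length)


_GT_STRING = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCFv4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbspopgen\n")
        if gm.total_sequence_length is not None:
            fh.write(
                f"##total_sequence_length={gm.total_sequence_length}\n"
            )
        for chrom in dict.fromkeys(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        loci = gm.loci
        for j in range(gm.n_loci):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.calls[:, j])
            fh.write(
                f"{loci.chrom[j]}\t{loci.pos[j]}\t.\t{loci.ref[j]}\t"
                f"{loci.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------
# Population map I/O
# ----------------------------------------------------------------------

def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a 3-column TSV (individual, population, group); '#' comments."""
    try:
        t = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise GenotypeError(f"empty population map file {path}") from None
    if t.shape[1] < 3:
        raise GenotypeError(
            f"population map {path} needs >=3 tab-separated columns"
        )
    t = t.iloc[:, :3]
    t.columns = ["individual", "population", "group"]
    return PopulationMap(t)


def write_popmap(pm: PopulationMap, path: str | os.PathLike) -> None:
    pm.table.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# Locus filtering (dataset-construction rule)
# ----------------------------------------------------------------------

def filter_loci(gm: GenotypeMatrix, pm: PopulationMap, *,
                min_populations: int, min_fraction: float,
                level: str = "population") -> GenotypeMatrix:
    """Keep loci genotyped in >= ``min_fraction`` of individuals in each
    of >= ``min_populations`` units.

    ``level`` selects the counting unit: ``"population"`` (default,
    Stacks ``-p``/``-r`` semantics) or ``"group"``.  The fraction
    comparison is done on exact rationals (calls/individuals >= the
    decimal value of ``min_fraction``), so e.g. 7/10 >= 0.70 holds
    exactly.
    """
    pm.check_covers(gm)
    if level not in ("population", "group"):
        raise GenotypeError(f"unknown level {level!r}")
    units = pm.populations if level == "population" else pm.groups
    if min_populations > len(units):
        raise GenotypeError(
            f"min_populations={min_populations} exceeds number of "
            f"{level}s ({len(units)})"
        )
    frac = Fraction(str(min_fraction))
    called = gm.called()
    n_ok = np.zeros(gm.n_loci, dtype=int)
    for unit in units:
        kw = {"population": unit} if level == "population" else {"group": unit}
        idx = pm.indices(gm, **kw)
        if len(idx) == 0:
            continue
        counts = called[idx, :].sum(axis=0)
        ok = np.array(
            [Fraction(int(c), len(idx)) >= frac for c in counts]
        )
        n_ok += ok
    keep = n_ok >= min_populations
    return gm.subset_loci(keep)
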