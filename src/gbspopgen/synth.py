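"""Study-shaped synthetic datasets and hand-constructed fixtures.

Templates mirror the shapes of the real GBS datasets this pipeline is
designed for: a boundary-region dataset of four groups of five
single-individual populations (~1,000 SNPs), a two-deme local dataset
of six diploids per deme (~700 SNPs), and a multi-group statistics
dataset.  Each generated dataset carries a truth record (generating
scenario and parameters) so recovery experiments read the truth only
from that record.

Hand-constructed fixtures ship their expected statistics for oracle
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap, write_popmap, write_vcf
from .scenarios import build_scenarios
from .simulate import simulate_snps

# ----------------------------------------------------------------------
# Templates
# ----------------------------------------------------------------------

# GBS tags average ~19 bp of surveyed sequence per retained SNP in the
# study-shaped datasets; used to set total_sequence_length.
BP_PER_SNP = 19


@dataclass
class StudyTemplate:
    name: str
    scenario: str                       # key into build_scenarios()
    groups: dict[str, int]              # group -> diploid count
    populations_per_group: int          # label partitioning inside group
    n_loci: int
    missingness: float
    true_params: dict[str, float]
    seed: int = 0
    locus_dropout: bool = False         # beta-distributed per-locus rate

    def __post_init__(self) -> None:
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0,1)")
        if any(c <= 0 for c in self.groups.values()):
            raise ValueError("diploid counts must be positive")


# defaults follow the study shapes; true parameters are the demographic
# point estimates the pipeline itself reports on such data
_HZ2_TRUTH = {
    "N_njpn": 825_000.0, "N_tajima_tango": 613_000.0,
    "N_kyushu": 1_210_000.0, "N_honshu": 1_490_000.0,
    "N_ancestor": 432_000.0,
    "t1": 566_000.0, "t2": 1_050_000.0, "t3": 4_560_000.0,
}
_LOCAL_TRUTH = {
    "N_s_saga": 1_326_000.0, "N_n_saga": 1_224_000.0, "t": 510_000.0,
}


def templates() -> dict[str, StudyTemplate]:
    return {
        "hz2-like": StudyTemplate(
            name="hz2-like", scenario="III",
            groups={"N.JPN": 5, "Tajima-Tango": 5, "Kyushu": 5,
                    "Honshu": 5},
            populations_per_group=5, n_loci=1014, missingness=0.0,
            true_params=dict(_HZ2_TRUTH),
        ),
        "local-like": StudyTemplate(
            name="local-like", scenario="out_of_nk",
            groups={"S.Saga": 6, "N.Saga": 6},
            populations_per_group=1, n_loci=698, missingness=0.0,
            true_params=dict(_LOCAL_TRUTH),
        ),
        "popstat-like": StudyTemplate(
            name="popstat-like", scenario="III",
            groups={"N.JPN": 6, "Tajima-Tango": 5, "Kyushu": 3,
                    "Honshu": 6},
            populations_per_group=1, n_loci=800, missingness=0.0,
            true_params=dict(_HZ2_TRUTH),
        ),
    }


def generate(template: StudyTemplate | str, *, seed: int | None = None,
             n_loci: int | None = None, missingness: float | None = None,
             ) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Simulate a study-shaped dataset with known truth.

    Returns (genotype matrix, population map, truth record); the truth
    record carries the scenario name, the true parameters, the seed and
    the dataset shape.  Deterministic given the seed.
    """
    if isinstance(template, str):
        try:
            template = templates()[template]
        except KeyError:
            raise ValueError(
                f"unknown template {template!r}; have "
                f"{sorted(templates())}"
            ) from None
    seed = template.seed if seed is None else seed
    n_loci = template.n_loci if n_loci is None else n_loci
    missingness = (
        template.missingness if missingness is None else missingness
    )
    sc = build_scenarios()[template.scenario]

    names: list[str] = []
    rows = []
    for g, count in template.groups.items():
        npop = max(1, template.populations_per_group)
        for k in range(count):
            pop = f"{g}-P{(k % npop) + 1}"
            ind = f"{g}-{k + 1}"
            names.append(ind)
            rows.append({"individual": ind, "population": pop, "group": g})
    pm = PopulationMap(pd.DataFrame(rows))

    gm = simulate_snps(
        sc, template.true_params, n_loci,
        {g: c for g, c in template.groups.items()},
        seed, individual_names=names,
        total_sequence_length=n_loci * BP_PER_SNP,
    )
    rng = np.random.default_rng(seed + 1)
    if missingness > 0:
        if template.locus_dropout:
            # locus-structured dropout: per-locus rate ~ Beta with the
            # requested mean and moderate dispersion
            a = 2.0
            b = a * (1 - missingness) / missingness
            rates = rng.beta(a, b, size=gm.n_loci)
            drop = rng.random(gm.calls.shape) < rates[None, :]
        else:
            drop = rng.random(gm.calls.shape) < missingness
        calls = gm.calls.copy()
        calls[drop] = -1
        gm = GenotypeMatrix(gm.individuals, gm.loci, calls,
                            total_sequence_length=gm.total_sequence_length)
    truth = {
        "template": template.name,
        "scenario": template.scenario,
        "true_params": dict(template.true_params),
        "seed": int(seed),
        "n_loci": int(n_loci),
        "missingness": float(missingness),
        "groups": {g: int(c) for g, c in template.groups.items()},
    }
    return gm, pm, truth


def write_dataset(gm: GenotypeMatrix, pm: PopulationMap, truth: dict,
                  outdir) -> None:
    """Persist a generated dataset as VCF + popmap TSV + truth JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_vcf(gm, os.path.join(outdir, "genotypes.vcf"))
    write_popmap(pm, os.path.join(outdir, "popmap.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


# ----------------------------------------------------------------------
# Hand-constructed fixtures
# ----------------------------------------------------------------------


def _matrix(groups: dict[str, list[list[int]]], chrom_per_locus=None,
            total_length=None):
    """Build (gm, pm) from per-group dosage row lists."""
    names, rows, calls = [], [], []
    for g, mat in groups.items():
        for k, row in enumerate(mat):
            names.append(f"{g}-{k + 1}")
            rows.append(
                {"individual": f"{g}-{k + 1}", "population": f"{g}-P1",
                 "group": g}
            )
            calls.append(row)
    calls = np.asarray(calls, dtype=np.int8)
    n_loci = calls.shape[1]
    if chrom_per_locus is None:
        chrom_per_locus = ["chr1"] * n_loci
    pos, seen = [], {}
    for c in chrom_per_locus:
        seen[c] = seen.get(c, 0) + 1
        pos.append(1000 * seen[c])
    loci = pd.DataFrame(
        {"chrom": chrom_per_locus, "pos": pos, "ref": "A", "alt": "T"}
    )
    gm = GenotypeMatrix(names, loci, calls, total_sequence_length=total_length)
    pm = PopulationMap(pd.DataFrame(rows))
    return gm, pm


def make_fixture(name: str):
    """Small hand-constructed (gm, pm, expected) fixtures.

    ``expected`` ships the precomputed statistics the fixture was built
    to exhibit.
    """
    if name == "sharing-811":
        # 10 trio SNPs: 8 shared(A,B), 1 shared(A,C), 1 shared(B,C)
        a = [[2] * 8 + [2] + [0], [2] * 8 + [2] + [0]]
        b = [[2] * 8 + [0] + [2], [2] * 8 + [0] + [2]]
        c = [[0] * 8 + [2] + [2], [0] * 8 + [2] + [2]]
        gm, pm = _matrix({"A": a, "B": b, "C": c})
        expected = {
            "groups": ("A", "B", "C"),
            "counts": {"shared(A,B)": 8, "shared(A,C)": 1,
                       "shared(B,C)": 1},
            "proportions": {"shared(A,B)": 0.8, "shared(A,C)": 0.1,
                            "shared(B,C)": 0.1},
        }
        return gm, pm, expected
    if name == "mono":
        g = [[0, 0, 0, 0], [0, 0, 0, 0]]
        gm, pm = _matrix({"A": g, "B": g}, total_length=1000)
        return gm, pm, {"pi": 0.0, "n_polymorphic": 0}
    if name == "het23":
        # one individual with exactly 23 heterozygous sites, 1000 bp
        row = [1] * 23 + [0] * 7
        other = [0] * 30
        gm, pm = _matrix({"A": [row, other]}, total_length=1000)
        return gm, pm, {"heterozygosity": {"A-1": 0.023, "A-2": 0.0}}
    if name == "filter-rates":
        # 5 loci with per-population call rates 1.0, .6, .7, .65, .9
        # in each of two 20-individual populations
        per_locus = [20, 12, 14, 13, 18]
        cols = []
        for called in per_locus:
            cols.append([0] * called + [-1] * (20 - called))
        mat = np.array(cols).T.tolist()  # 20 x 5
        gm, pm = _matrix({"A": mat, "B": mat})
        return gm, pm, {"kept_at_0.66": [0, 2, 4], "kept_at_0.7": [0, 2, 4]}
    raise ValueError(
        f"unknown fixture {name!r}; have sharing-811, mono, het23, "
        "filter-rates"
    )
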