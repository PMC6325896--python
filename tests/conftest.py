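import numpy as np
import pandas as pd
import pytest

from gbspopgen.genotypes import GenotypeMatrix, PopulationMap


def build_matrix(calls, *, chroms=None, total_length=None, groups=None):
    """Construct a GenotypeMatrix (+ map) from a plain dosage list.

    ``calls`` is individuals x loci; ``groups`` maps group name ->
    number of consecutive individuals (defaults to one group "G").
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    if chroms is None:
        chroms = ["chr1"] * n_loci
    pos, seen = [], {}
    for c in chroms:
        seen[c] = seen.get(c, 0) + 1
        pos.append(100 * seen[c])
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "T"}
    )
    if groups is None:
        groups = {"G": n_ind}
    names, rows = [], []
    for g, count in groups.items():
        for k in range(count):
            nm = f"{g}-{k + 1}"
            names.append(nm)
            rows.append(
                {"individual": nm, "population": f"{g}-P1", "group": g}
            )
    assert len(names) == n_ind
    gm = GenotypeMatrix(names, loci, calls, total_sequence_length=total_length)
    pm = PopulationMap(pd.DataFrame(rows))
    return gm, pm


@pytest.fixture
def tiny_vcf(tmp_path):
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def triallelic_vcf(tmp_path):
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
chr1\t100\t.\tA\tT,C\t.\tPASS\t.\tGT\t0/1\t1/2
"""
    path = tmp_path / "tri.vcf"
    path.write_text(text)
    return path
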