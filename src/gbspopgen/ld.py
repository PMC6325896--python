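"""Windowed pairwise-r2 LD pruning (plink ``--indep-pairwise`` style).

r2 is the squared Pearson correlation of alt-allele dosages over
pairwise-complete individuals.  Pruning removes one member of each
same-chromosome pair closer than the physical window with r2 above the
threshold, until no such pair remains; the removed member is chosen
uniformly at random (seeded) by default, or by lower minor-allele
frequency with ``removal="maf"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, GenotypeError


@dataclass
class PruneConfig:
    window_kb: float = 12.5
    step: int = 5
    r2_max: float = 0.2
    seed: int = 0
    removal: str = "random"  # or "maf"

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0,1]")
        if self.removal not in ("random", "maf"):
            raise ValueError("removal must be 'random' or 'maf'")


def pairwise_r2(gm: GenotypeMatrix, i: int, j: int) -> float | None:
    """Squared Pearson correlation of dosages at loci ``i`` and ``j``.

    Returns ``None`` when either locus is monomorphic on the
    pairwise-complete set (undefined correlation).  Raises if the loci
    are on different chromosomes.
    """
    if gm.loci["chrom"].iat[i] != gm.loci["chrom"].iat[j]:
        raise GenotypeError("pairwise_r2 requires loci on one chromosome")
    x = gm.calls[:, i].astype(float)
    y = gm.calls[:, j].astype(float)
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_pairs(chrom_pos: np.ndarray, window_bp: float):
    """All index pairs (i<j) within the physical window."""
    n = len(chrom_pos)
    for i in range(n):
        for j in range(i + 1, n):
            if chrom_pos[j] - chrom_pos[i] > window_bp:
                break
            yield i, j


def prune(gm: GenotypeMatrix, cfg: PruneConfig) -> GenotypeMatrix:
    """LD-prune a genotype matrix; deterministic given ``cfg.seed``.

    The output contains no same-chromosome pair within ``window_kb``
    with r2 > ``r2_max``; locus order is preserved.
    """
    rng = np.random.default_rng(cfg.seed)
    window_bp = cfg.window_kb * 1000.0
    keep = np.ones(gm.n_loci, dtype=bool)
    chroms = gm.loci["chrom"].to_numpy()
    positions = gm.loci["pos"].to_numpy()

    # minor-allele frequency (for removal="maf")
    called = gm.called()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gm.calls, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1
        )
    maf = np.minimum(p, 1 - p)

    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        pos = positions[cidx]
        changed = True
        while changed:
            changed = False
            retained = [k for k in range(len(cidx)) if keep[cidx[k]]]
            for a in range(len(retained)):
                i = retained[a]
                for b in range(a + 1, len(retained)):
                    j = retained[b]
                    if pos[j] - pos[i] > window_bp:
                        break
                    r2 = pairwise_r2(gm, int(cidx[i]), int(cidx[j]))
                    if r2 is not None and r2 > cfg.r2_max:
                        gi, gj = int(cidx[i]), int(cidx[j])
                        if cfg.removal == "maf" and maf[gi] != maf[gj]:
                            drop = gi if maf[gi] < maf[gj] else gj
                        else:
                            drop = gi if rng.integers(2) == 0 else gj
                        keep[drop] = False
                        changed = True
                        break
                if changed:
                    break
    return gm.subset_loci(keep)


def audit(gm: GenotypeMatrix, cfg: PruneConfig) -> list[tuple[int, int, float]]:
    """Exhaustively list surviving same-window pairs with r2 > r2_max.

    An LD-pruned matrix must yield an empty list.
    """
    window_bp = cfg.window_kb * 1000.0
    offenders = []
    chroms = gm.loci["chrom"].to_numpy()
    positions = gm.loci["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        pos = positions[cidx]
        for i, j in _window_pairs(pos, window_bp):
            r2 = pairwise_r2(gm, int(cidx[i]), int(cidx[j]))
            if r2 is not None and r2 > cfg.r2_max:
                offenders.append((int(cidx[i]), int(cidx[j]), r2))
    return offenders
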