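"""The f3 admixture statistic with block-jackknife standard errors.

f3(X; Y, Z) tests whether population X derives from a mixture of sources
related to Y and Z.  Per site j with sample allele frequencies x, y, z and
n_X non-missing chromosomes in X,

    f3_j = (x - y)(x - z) - x(1 - x) / (n_X - 1),

where the second term removes the bias from sampling noise in x.  The
statistic is the mean over contributing sites; its standard error comes
from a delete-one block jackknife over consecutive 50-SNP blocks (a short
terminal block is retained and weighted equally), and Z = f3 / SE.
Significantly negative values indicate admixture of X.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix


@dataclass
class F3Result:
    X: str
    Y: str
    Z: str
    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    def __str__(self) -> str:
        return (
            f"f3({self.X}; {self.Y}, {self.Z}) = {self.f3:.6g} "
            f"(SE {self.se:.3g}, Z = {self.z:.3f}, {self.n_blocks} blocks)"
        )


def _freq_and_count(g: GenotypeMatrix, rows: np.ndarray):
    sub = g.dosage[rows]
    called = sub != MISSING
    n_chrom = (2 * called.sum(axis=0)).astype(float)
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom


def f3_statistic(
    g: GenotypeMatrix,
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    block_size: int = 50,
    labels: tuple[str, str, str] = ("X", "Y", "Z"),
) -> F3Result:
    """f3(X; Y, Z) with delete-one 50-SNP-block jackknife SE.

    Sites are used in matrix order (assumed sorted by scaffold/position);
    a site contributes only if X has >= 2 chromosomes called and Y, Z at
    least one each.
    """
    x, nx = _freq_and_count(g, np.asarray(X, dtype=int))
    y, ny = _freq_and_count(g, np.asarray(Y, dtype=int))
    z, nz = _freq_and_count(g, np.asarray(Z, dtype=int))
    use = (nx >= 2) & (ny >= 1) & (nz >= 1)
    if not use.any():
        raise ValueError("no contributing sites for f3")
    xj, yj, zj, nxj = x[use], y[use], z[use], nx[use]
    per_site = (xj - yj) * (xj - zj) - xj * (1.0 - xj) / (nxj - 1.0)

    f3 = float(per_site.mean())
    n_sites = len(per_site)
    n_blocks = int(np.ceil(n_sites / block_size))
    if n_blocks >= 2:
        block_of = np.arange(n_sites) // block_size
        total = per_site.sum()
        loo = np.empty(n_blocks)
        for b in range(n_blocks):
            in_b = block_of == b
            loo[b] = (total - per_site[in_b].sum()) / (n_sites - in_b.sum())
        mean_loo = loo.mean()
        se = float(np.sqrt((n_blocks - 1.0) / n_blocks * ((loo - mean_loo) ** 2).sum()))
    else:
        se = float("nan")
    zscore = f3 / se if se and se > 0 else float("nan")
    return F3Result(labels[0], labels[1], labels[2], f3, se, zscore, n_blocks, n_sites)


def enumerate_f3_tests(
    regions: list[str], dedup: bool = False
) -> list[tuple[str, str, str]]:
    """All ordered (X; Y, Z) triples of distinct regions.

    n regions give n(n-1)(n-2) triples; with ``dedup`` the symmetric (Y, Z)
    order is collapsed, halving the count.
    """
    regions = list(regions)
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    triples = []
    for X in regions:
        others = [r for r in regions if r != X]
        if dedup:
            for Y, Z in itertools.combinations(others, 2):
                triples.append((X, Y, Z))
        else:
            for Y, Z in itertools.permutations(others, 2):
                triples.append((X, Y, Z))
    return triples


def f3_all(
    g: GenotypeMatrix,
    region_rows: dict[str, np.ndarray],
    block_size: int = 50,
    dedup: bool = False,
) -> list[F3Result]:
    """Run f3 for every region triple; returns results in enumeration order."""
    results = []
    for X, Y, Z in enumerate_f3_tests(sorted(region_rows), dedup=dedup):
        results.append(
            f3_statistic(
                g, region_rows[X], region_rows[Y], region_rows[Z],
                block_size=block_size, labels=(X, Y, Z),
            )
        )
    return results
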