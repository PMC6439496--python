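"""Site- and sample-level genotype filters.

The canonical order, applied by :func:`filter_chain`, is: biallelic SNPs ->
excess heterozygosity -> sample missingness -> genotype-quality masking ->
site missingness -> rare alleles -> LD pruning.  Boundary semantics follow
the study design exactly: the heterozygosity cut is inclusive at 0.6,
sample missingness is strict (> 0.80 dropped), site missingness is strict
(< 0.30 kept), and the MAF cut is inclusive (>= 0.05 kept).

The sex-linkage and close-kin screens are principled stand-ins (the original
procedures are not public): a per-site test for heterozygotes confined to
one sex (the female-hemizygous pattern of Z-linked loci in birds), and the
KING-robust method-of-moments kinship estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeMatrix, SampleRecord


@dataclass
class FilterReport:
    """Attrition record for one filter step."""

    step: str
    sites_in: int
    sites_out: int
    samples_in: int
    samples_out: int
    dropped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sites_out > self.sites_in or self.samples_out > self.samples_in:
            raise ValueError("filter cannot add sites or samples")


def _report(step: str, before: GenotypeMatrix, after: GenotypeMatrix,
            dropped: list[str] | None = None) -> FilterReport:
    return FilterReport(
        step, before.n_sites, after.n_sites,
        before.n_samples, after.n_samples, dropped or [],
    )


def filter_biallelic_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only biallelic SNP sites; the sample set is unchanged."""
    keep = [i for i, s in enumerate(g.sites) if s.is_snp and s.is_biallelic]
    return g.take_sites(keep)


def filter_excess_heterozygosity(g: GenotypeMatrix, max_het: float = 0.6) -> GenotypeMatrix:
    """Drop sites with observed heterozygosity >= ``max_het`` (inclusive).

    Such sites are likely collapsed paralogs rather than allelic variation.
    All-missing sites are dropped here (no statistic is defined for them).
    """
    called = g.called()
    n_called = called.sum(axis=0)
    n_het = ((g.dosage == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    keep = np.flatnonzero((n_called > 0) & (het < max_het))
    return g.take_sites(keep)


def mask_low_quality(g: GenotypeMatrix, min_gq: float = 10.0) -> GenotypeMatrix:
    """Set genotypes with quality below ``min_gq`` to missing (GQ >= 10 kept).

    Genotypes without a quality value are never masked (a warning is issued
    if the matrix carries no qualities at all).
    """
    out = g.copy()
    has_q = np.isfinite(out.quality)
    if not has_q.any() and out.n_sites > 0:
        warnings.warn("no genotype qualities present; mask_low_quality is a no-op")
        return out
    mask = has_q & (out.quality < min_gq)
    out.dosage[mask] = MISSING
    out.quality[mask] = np.nan
    return out


def filter_sample_missingness(
    g: GenotypeMatrix, max_missing: float = 0.80
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop samples with MORE than ``max_missing`` missing genotypes (strict)."""
    frac = g.sample_missing_fraction()
    keep = np.flatnonzero(frac <= max_missing)
    dropped = [g.sample_ids[i] for i in np.flatnonzero(frac > max_missing)]
    out = g.take_samples(keep)
    return out, _report("sample_missingness", g, out, dropped)


def filter_site_missingness(g: GenotypeMatrix, max_missing: float = 0.30) -> GenotypeMatrix:
    """Keep sites with missing fraction strictly below ``max_missing``."""
    frac = g.site_missing_fraction()
    return g.take_sites(np.flatnonzero(frac < max_missing))


def filter_rare_alleles(
    g: GenotypeMatrix, mode: str = "maf_threshold", maf: float = 0.05
) -> GenotypeMatrix:
    """Remove rare variants, by singleton elimination or a MAF threshold.

    ``drop_singletons`` removes sites where the minor allele is observed on
    exactly one chromosome (one heterozygote, no other carrier), and
    monomorphic sites.  ``maf_threshold`` keeps sites with MAF >= ``maf``
    (inclusive) over non-missing genotypes.
    """
    called = g.called()
    alt = np.where(called, g.dosage, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    minor = np.minimum(alt, total - alt)
    if mode == "drop_singletons":
        keep = minor >= 2
    elif mode == "maf_threshold":
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
        # guard against float round-off at the inclusive boundary
        keep = freq >= maf - 1e-12
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep &= total > 0
    return g.take_sites(np.flatnonzero(keep))


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 500_000,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Greedy scan keeping sites whose genotype r^2 with every retained site
    within ``window_bp`` on the same scaffold is <= ``r2_max``.

    Deterministic given the input order; the seed parameter is accepted for
    interface stability but the greedy scan uses none.
    """
    order = sorted(range(g.n_sites), key=lambda i: (g.sites[i].scaffold, g.sites[i].position))
    d = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))
    kept: list[int] = []
    kept_by_scaffold: dict[str, list[int]] = {}
    for j in order:
        site = g.sites[j]
        candidates = [
            i for i in kept_by_scaffold.get(site.scaffold, [])
            if site.position - g.sites[i].position < window_bp
        ]
        ok = True
        for i in candidates:
            both = np.isfinite(d[:, i]) & np.isfinite(d[:, j])
            if both.sum() < 3:
                continue
            x, y = d[both, i], d[both, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
            kept_by_scaffold.setdefault(site.scaffold, []).append(j)
    return g.take_sites(sorted(kept))


def detect_sex_linked_loci(
    g: GenotypeMatrix, samples: list[SampleRecord], alpha: float = 0.01
) -> np.ndarray:
    """Flag sites whose heterozygosity differs between known sexes.

    In birds females are ZW, so a Z-linked locus shows heterozygotes only
    among males; a per-site Fisher exact test on heterozygote counts by sex
    flags such loci.  Returns a boolean array over sites.
    """
    sex_of = {s.sample_id: s.sex for s in samples}
    males = np.array([sex_of.get(sid) == "M" for sid in g.sample_ids])
    females = np.array([sex_of.get(sid) == "F" for sid in g.sample_ids])
    flags = np.zeros(g.n_sites, dtype=bool)
    if males.sum() < 3 or females.sum() < 3:
        warnings.warn("fewer than 3 samples of each known sex; no sex-linkage flags")
        return flags
    called = g.called()
    het = g.dosage == 1
    for j in range(g.n_sites):
        m_called = int((called[:, j] & males).sum())
        f_called = int((called[:, j] & females).sum())
        if m_called == 0 or f_called == 0:
            continue
        m_het = int((het[:, j] & males).sum())
        f_het = int((het[:, j] & females).sum())
        table = [[m_het, m_called - m_het], [f_het, f_called - f_het]]
        if stats.fisher_exact(table)[1] < alpha:
            flags[j] = True
    return flags


def kinship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise KING-robust kinship estimates.

    phi_ij = (N_het,het - 2 N_opposite_hom) / (N_het(i) + N_het(j)) over
    sites called in both samples; a duplicated sample gives ~0.5 and a
    parent-offspring pair ~0.25.
    """
    n = g.n_samples
    phi = np.zeros((n, n))
    d = g.dosage
    called = g.called()
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            di, dj = d[i, both], d[j, both]
            n_hh = int(((di == 1) & (dj == 1)).sum())
            n_opp = int((((di == 0) & (dj == 2)) | ((di == 2) & (dj == 0))).sum())
            n_het_i = int((di == 1).sum())
            n_het_j = int((dj == 1).sum())
            denom = n_het_i + n_het_j
            phi[i, j] = phi[j, i] = (
                (n_hh - 2.0 * n_opp) / denom if denom > 0 else 0.0
            )
    return phi


def detect_close_kin(
    g: GenotypeMatrix, threshold: float = 0.177
) -> list[tuple[str, str, float]]:
    """Sample pairs whose kinship exceeds ``threshold`` (1st/2nd-degree cut).

    The caller drops one member of each pair; :func:`drop_kin` applies the
    deterministic rule of dropping the sample with more missing data.
    """
    phi = kinship_matrix(g)
    pairs = []
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            if phi[i, j] > threshold:
                pairs.append((g.sample_ids[i], g.sample_ids[j], float(phi[i, j])))
    return pairs


def drop_kin(
    g: GenotypeMatrix, pairs: list[tuple[str, str, float]]
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop, from each flagged pair, the sample with more missing data."""
    miss = dict(zip(g.sample_ids, g.sample_missing_fraction()))
    to_drop: set[str] = set()
    for a, b, _ in pairs:
        if a in to_drop or b in to_drop:
            continue
        # ties broken toward the later sample id for determinism
        to_drop.add(a if (miss[a], a) > (miss[b], b) else b)
    keep = [i for i, s in enumerate(g.sample_ids) if s not in to_drop]
    out = g.take_samples(keep)
    return out, _report("close_kin", g, out, sorted(to_drop))


def filter_chain(
    g: GenotypeMatrix,
    mode: str = "maf_threshold",
    max_het: float = 0.6,
    max_sample_missing: float = 0.80,
    min_gq: float = 10.0,
    max_site_missing: float = 0.30,
    maf: float = 0.05,
    prune: bool = True,
    r2_max: float = 0.2,
    window_bp: int = 500_000,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Apply the full filter chain in the canonical order, recording attrition."""
    reports: list[FilterReport] = []

    step = filter_biallelic_snps(g)
    reports.append(_report("biallelic_snps", g, step))
    g = step

    step = filter_excess_heterozygosity(g, max_het)
    reports.append(_report("excess_heterozygosity", g, step))
    g = step

    g, rep = filter_sample_missingness(g, max_sample_missing)
    reports.append(rep)

    step = mask_low_quality(g, min_gq)
    reports.append(_report("gq_mask", g, step))
    g = step

    step = filter_site_missingness(g, max_site_missing)
    reports.append(_report("site_missingness", g, step))
    g = step

    step = filter_rare_alleles(g, mode=mode, maf=maf)
    reports.append(_report(f"rare_alleles[{mode}]", g, step))
    g = step

    if prune:
        step = ld_prune(g, r2_max=r2_max, window_bp=window_bp)
        reports.append(_report("ld_prune", g, step))
        g = step
    return g, reports
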