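"""Ancestry-informative marker (AIM) panel design and assay concordance.

Candidate SNPs are ranked by per-site F_ST between the two reference
clusters after removing sites with pooled minor allele frequency below
0.05; the assay design filters then accept sites top-down that have at
least 30 bp of clean flanking sequence (no non-rare variant within the
flank) and come from distinct scaffolds, stopping at the panel size.
Cross-platform concordance compares genotypes called on the same samples
and sites by two technologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SiteRecord


@dataclass
class AimPanel:
    """Ordered panel of high-F_ST sites with reference allele frequencies."""

    sites: list[SiteRecord]
    site_index: list[int] = field(default_factory=list)
    fst_rank: list[int] = field(default_factory=list)
    fst: list[float] = field(default_factory=list)
    p_ref1: np.ndarray | None = None
    p_ref2: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "scaffold": [s.scaffold for s in self.sites],
                "position": [s.position for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "rank": self.fst_rank,
                "fst": self.fst,
            }
        )
        if self.p_ref1 is not None:
            df["p_ref1"] = self.p_ref1
            df["p_ref2"] = self.p_ref2
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AimPanel":
        df = pd.read_csv(path, sep="\t")
        sites = [
            SiteRecord(r.scaffold, int(r.position), r.ref, r.alt)
            for r in df.itertuples(index=False)
        ]
        return cls(
            sites=sites,
            site_index=list(range(len(sites))),
            fst_rank=list(df["rank"]),
            fst=list(df["fst"]),
            p_ref1=df["p_ref1"].to_numpy() if "p_ref1" in df else None,
            p_ref2=df["p_ref2"].to_numpy() if "p_ref2" in df else None,
        )


def rank_candidates(
    fst_table: pd.DataFrame, g: GenotypeMatrix, maf: float = 0.05
) -> pd.DataFrame:
    """Rank sites by descending per-site F_ST after a pooled-MAF screen.

    ``fst_table`` is the per-site output of :func:`~goshawkpop.differentiation.wc_fst`
    aligned with ``g``'s sites.  Sites with pooled MAF < ``maf`` or an
    undefined ratio are removed; ties break by (scaffold, position).
    """
    pooled_maf = g.minor_allele_freq()
    df = fst_table.copy()
    df["site_index"] = np.arange(len(df))
    df["pooled_maf"] = pooled_maf
    df = df[(df["pooled_maf"] >= maf - 1e-12) & np.isfinite(df["ratio"])]
    if df.empty:
        raise ValueError("no candidate sites remain after the MAF filter")
    df = df.sort_values(
        ["ratio", "scaffold", "position"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def apply_design_filters(
    ranked: pd.DataFrame,
    g: GenotypeMatrix,
    flank_bp: int = 30,
    panel_size: int = 11,
    rare_maf: float = 0.05,
) -> AimPanel:
    """Greedy top-down panel selection under the assay design constraints.

    A candidate is accepted iff (i) both stored flanks are at least
    ``flank_bp`` long, (ii) no other non-rare variant (pooled MAF >=
    ``rare_maf`` anywhere in the dataset) lies within ``flank_bp`` of it,
    and (iii) its scaffold is not already used.  Selection stops at
    ``panel_size``; a smaller panel is returned with a warning if the
    candidates run out.
    """
    pooled_maf = g.minor_allele_freq()
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for j, s in enumerate(g.sites):
        by_scaffold.setdefault(s.scaffold, []).append((s.position, j))

    chosen: list[int] = []
    ranks: list[int] = []
    fsts: list[float] = []
    used_scaffolds: set[str] = set()
    for row in ranked.itertuples(index=False):
        if len(chosen) >= panel_size:
            break
        j = int(row.site_index)
        site = g.sites[j]
        if site.scaffold in used_scaffolds:
            continue
        if len(site.flank_left) < flank_bp or len(site.flank_right) < flank_bp:
            continue
        crowded = False
        for pos, other in by_scaffold[site.scaffold]:
            if other == j or abs(pos - site.position) > flank_bp:
                continue
            if pooled_maf[other] >= rare_maf - 1e-12:
                crowded = True
                break
        if crowded:
            continue
        chosen.append(j)
        ranks.append(int(row.rank))
        fsts.append(float(row.ratio))
        used_scaffolds.add(site.scaffold)
    if len(chosen) < panel_size:
        warnings.warn(
            f"only {len(chosen)} sites satisfy the design filters "
            f"(requested {panel_size})"
        )
    return AimPanel(
        sites=[g.sites[j] for j in chosen],
        site_index=chosen,
        fst_rank=ranks,
        fst=fsts,
    )


def panel_frequencies(
    panel: AimPanel, g: GenotypeMatrix, ref_group1: np.ndarray, ref_group2: np.ndarray
) -> AimPanel:
    """Attach ALT-allele frequencies from the two reference groups.

    Raises if any panel site is entirely missing in a reference group.
    """
    p1 = g.alt_allele_freq(np.asarray(ref_group1, dtype=int))
    p2 = g.alt_allele_freq(np.asarray(ref_group2, dtype=int))
    freqs1, freqs2 = [], []
    for j, site in zip(panel.site_index, panel.sites):
        if not np.isfinite(p1[j]) or not np.isfinite(p2[j]):
            raise ValueError(
                f"panel site {site.scaffold}:{site.position} unobserved in a "
                "reference group"
            )
        freqs1.append(p1[j])
        freqs2.append(p2[j])
    panel.p_ref1 = np.asarray(freqs1)
    panel.p_ref2 = np.asarray(freqs2)
    return panel


@dataclass
class ConcordanceReport:
    n_compared: int
    n_discrepant: int
    rate_pct: float            # exact percentage
    het_vs_hom: int
    opposite_hom: int

    @property
    def rate_pct_display(self) -> float:
        """Percentage rounded half-up to two decimals (as printed)."""
        import decimal

        return float(
            decimal.Decimal(self.rate_pct).quantize(
                decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
            )
        )


def genotype_concordance(gA: GenotypeMatrix, gB: GenotypeMatrix) -> ConcordanceReport:
    """Discrepancy rate between two genotype callsets on shared samples/sites.

    Only (sample, site) pairs non-missing in both datasets count; each
    discrepancy is classified as het-vs-hom or opposite-homozygote.
    """
    shared_samples = [s for s in gA.sample_ids if s in set(gB.sample_ids)]
    keyB = {(s.scaffold, s.position): j for j, s in enumerate(gB.sites)}
    shared_sites = [
        (i, keyB[(s.scaffold, s.position)])
        for i, s in enumerate(gA.sites)
        if (s.scaffold, s.position) in keyB
    ]
    if not shared_samples or not shared_sites:
        raise ValueError("no shared (sample, site) pairs between datasets")
    rowsA = gA.sample_index(shared_samples)
    rowsB = gB.sample_index(shared_samples)
    n_compared = n_disc = het_hom = opp_hom = 0
    for ja, jb in shared_sites:
        a = gA.dosage[rowsA, ja]
        b = gB.dosage[rowsB, jb]
        both = (a != MISSING) & (b != MISSING)
        n_compared += int(both.sum())
        diff = both & (a != b)
        n_disc += int(diff.sum())
        opp = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
        opp_hom += int(opp.sum())
        het_hom += int((diff & ~opp).sum())
    if n_compared == 0:
        raise ValueError("zero comparable genotype calls")
    return ConcordanceReport(
        n_compared, n_disc, 100.0 * n_disc / n_compared, het_hom, opp_hom
    )
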