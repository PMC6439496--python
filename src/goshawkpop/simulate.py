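"""Synthetic GBS-style SNP data and mtDNA alignments with planted structure.

The generator emulates the statistical features the downstream analyses
assume: a strongly drifted island population (Haida Gwaii-like) against a
weakly structured continental cluster, admixed individuals parameterized by
an ancestry index S and interclass heterozygosity H, tiered genotype
missingness and quality by DNA source (shed feathers far worse than tissue),
and an island mtDNA group constrained to very few haplotypes.

Regional allele frequencies follow the Balding-Nichols drift model: given an
ancestral frequency p and a region divergence parameter F, the regional
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose variance is F p(1-p) - so
the Weir-Cockerham F_ST between two regions with parameters F1, F2 has
expectation (F1+F2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, HaplotypeAlignment, SiteRecord

_DNA = np.array(list("ACGT"))

#: GBS sample sizes per North American sampling region (island first).
DEFAULT_REGION_SIZES = {
    "HG": 12, "AA": 17, "AK": 26, "BC": 11,
    "BCc": 5, "East": 29, "VI": 6, "WA": 13,
}

#: Drift parameters producing island-vs-continent F_ST in the 0.06-0.09
#: band and continental pairwise F_ST at or below 0.01.
DEFAULT_DRIFT = {
    "HG": 0.14, "AA": 0.004, "AK": 0.004, "BC": 0.004,
    "BCc": 0.004, "East": 0.004, "VI": 0.004, "WA": 0.004,
}


def _default_tiers() -> dict[str, dict[str, float]]:
    return {r: {"tissue": 0.8, "feather": 0.2} for r in DEFAULT_REGION_SIZES}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``drift_F`` maps region -> Balding-Nichols divergence in [0, 1);
    ``admixed_specs`` plants extra individuals as (region_label, S, H)
    triples drawing alleles from the two ``admix_sources`` reference
    frequency sets; ``missing_rates`` and ``gq_params`` (gamma shape, scale)
    are keyed by DNA source tier; ``mt_theta`` is the expected pairwise
    mtDNA difference count within a region.
    """

    n_sites: int = 5000
    region_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SIZES)
    )
    drift_F: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    admixed_specs: list[tuple[str, float, float]] = field(default_factory=list)
    admix_sources: tuple[str, str] = ("HG", "East")
    source_tiers: dict[str, dict[str, float]] = field(default_factory=_default_tiers)
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "tissue": 0.08, "blood": 0.08, "toepad": 0.50, "feather": 0.85,
        }
    )
    gq_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tissue": (8.0, 5.0), "blood": (8.0, 5.0),
            "toepad": (4.0, 4.0), "feather": (2.0, 6.0),
        }
    )
    n_scaffolds: int = 40
    site_spacing_bp: int = 151
    flank_bp: int = 40
    mt_length: int = 578
    mt_theta: float = 3.0
    island_region: str = "HG"
    island_n_haplotypes: int = 2
    island_hap_step: int = 1
    island_major_freq: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mt_length < 1:
            raise ValueError("mt_length must be >= 1")
        for r, n in self.region_sizes.items():
            if n < 1:
                raise ValueError(f"region size for {r} must be positive")
        for r, f in self.drift_F.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift_F[{r}]={f} outside [0, 1)")
        for r in self.region_sizes:
            if r not in self.drift_F:
                raise ValueError(f"no drift_F for region {r}")
        for tier, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {tier} outside [0, 1]")
        for region, mix in self.source_tiers.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"source mix for {region} must sum to 1")
        for region, S, H in self.admixed_specs:
            check_feasible(S, H)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the simulation."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def check_feasible(S: float, H: float) -> None:
    """Raise unless (S, H) lies in the ancestry triangle H <= 2 min(S, 1-S)."""
    if not (0.0 <= S <= 1.0 and 0.0 <= H <= 1.0):
        raise ValueError(f"(S={S}, H={H}) outside the unit square")
    if H > 2.0 * min(S, 1.0 - S) + 1e-12:
        raise ValueError(f"(S={S}, H={H}) violates H <= 2*min(S, 1-S)")


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes
# ---------------------------------------------------------------------------

def simulate_allele_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """Regional allele-frequency table (regions x sites) under drift.

    Ancestral frequencies are Uniform(0.05, 0.95) to keep sites informative
    and away from the boundaries; a region with F = 0 copies the ancestral
    frequency exactly.
    """
    rng = config.rng(0)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_sites)
    rows = {}
    for region in config.region_sizes:
        F = config.drift_F[region]
        if F == 0.0:
            rows[region] = p_anc.copy()
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            rows[region] = rng.beta(a, b)
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(config.n_sites))


def _make_sites(config: SimulationConfig, rng: np.random.Generator) -> list[SiteRecord]:
    per_scaffold = int(np.ceil(config.n_sites / config.n_scaffolds))
    sites = []
    for j in range(config.n_sites):
        scaf = f"scaffold_{j // per_scaffold + 1:03d}"
        pos = (j % per_scaffold) * config.site_spacing_bp + 100
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SiteRecord(
                scaffold=scaf,
                position=int(pos),
                ref=str(_DNA[ref]),
                alt=str(_DNA[alt]),
                flank_left="".join(rng.choice(_DNA, size=config.flank_bp)),
                flank_right="".join(rng.choice(_DNA, size=config.flank_bp)),
            )
        )
    return sites


def simulate_genotypes(
    freqs: pd.DataFrame, config: SimulationConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw diploid dosages for pure and planted-admixed individuals.

    Pure individuals draw Binomial(2, p_region) per site.  A planted
    (region, S, H) individual assigns each locus independently to the
    both-source-1 / one-each / both-source-2 ancestry class with
    probabilities (S - H/2, H, 1 - S - H/2) and then draws each allele copy
    from the corresponding source frequency.
    """
    rng = config.rng(1)
    sites = _make_sites(config, rng)
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    dosage_rows: list[np.ndarray] = []

    for region, n in config.region_sizes.items():
        mix = config.source_tiers.get(region, {"tissue": 1.0})
        tiers = list(mix)
        probs = np.array([mix[t] for t in tiers])
        p = freqs.loc[region].to_numpy()
        for i in range(n):
            sid = f"{region}_{i + 1:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "region": region,
                    "source": tiers[int(rng.choice(len(tiers), p=probs))],
                    "sex": "M" if i % 2 == 0 else "F",
                }
            )
            dosage_rows.append(rng.binomial(2, p).astype(np.int16))

    srcA, srcB = config.admix_sources
    if config.admixed_specs:
        pA = freqs.loc[srcA].to_numpy()
        pB = freqs.loc[srcB].to_numpy()
        for k, (region, S, H) in enumerate(config.admixed_specs):
            check_feasible(S, H)
            sid = f"{region}_adm{k + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "region": region, "source": "tissue",
                 "sex": "M" if k % 2 == 0 else "F"}
            )
            cls = rng.choice(3, size=config.n_sites, p=[S - H / 2.0, H, 1.0 - S - H / 2.0])
            copy1 = rng.random(config.n_sites) < np.where(cls == 2, pB, pA)
            copy2 = rng.random(config.n_sites) < np.where(cls == 0, pA, pB)
            dosage_rows.append((copy1.astype(np.int16) + copy2.astype(np.int16)))

    g = GenotypeMatrix(sample_ids, sites, np.stack(dosage_rows))
    meta = pd.DataFrame(meta_rows)
    return g, meta


def apply_quality_model(
    g: GenotypeMatrix, meta: pd.DataFrame, config: SimulationConfig
) -> GenotypeMatrix:
    """Mask genotypes at the sample's source-tier rate and attach GQ values.

    Retained genotypes get qualities from a discretized gamma distribution
    per tier; only their ordering relative to the GQ threshold matters
    downstream.  Matrix dimensions are unchanged.
    """
    rng = config.rng(2)
    out = g.copy()
    source_of = dict(zip(meta["sample_id"], meta["source"]))
    for i, sid in enumerate(out.sample_ids):
        tier = source_of[sid]
        rate = config.missing_rates.get(tier, 0.0)
        drop = rng.random(out.n_sites) < rate
        shape, scale = config.gq_params.get(tier, (8.0, 5.0))
        gq = np.floor(rng.gamma(shape, scale, size=out.n_sites))
        out.dosage[i, drop] = MISSING
        out.quality[i] = gq
        out.quality[i, out.dosage[i] == MISSING] = np.nan
    return out


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

def simulate_mtdna(config: SimulationConfig) -> HaplotypeAlignment:
    """Gap-free mtDNA alignment with a haplotype-poor island group.

    Continental regions follow a star-like coalescent approximation: each
    sequence carries Poisson(theta/2) private mutations at globally distinct
    positions, so the expected pairwise difference within a region is theta.
    The island region is constrained to ``island_n_haplotypes`` haplotypes,
    adjacent ones separated by ``island_hap_step`` mutations.
    """
    rng = config.rng(3)
    L = config.mt_length
    ancestral = "".join(rng.choice(_DNA, size=L))
    free_positions = list(rng.permutation(L))

    def mutate(seq: list[str], k: int) -> list[str]:
        seq = list(seq)
        for _ in range(k):
            if not free_positions:
                break  # finite sites exhausted; further mutations dropped
            pos = free_positions.pop()
            current = seq[pos]
            choices = [b for b in "ACGT" if b != current]
            seq[pos] = choices[int(rng.integers(3))]
        return seq

    sample_ids: list[str] = []
    sequences: list[str] = []
    regions: dict[str, str] = {}

    island_haps: list[str] = [ancestral]
    hap = list(ancestral)
    for _ in range(config.island_n_haplotypes - 1):
        hap = mutate(hap, config.island_hap_step)
        island_haps.append("".join(hap))

    for region, n in config.region_sizes.items():
        for i in range(n):
            sid = f"{region}_{i + 1:03d}"
            sample_ids.append(sid)
            regions[sid] = region
            if region == config.island_region:
                if config.island_n_haplotypes == 1:
                    idx = 0
                else:
                    major = rng.random() < config.island_major_freq
                    idx = 0 if major else 1 + int(
                        rng.integers(config.island_n_haplotypes - 1)
                    )
                sequences.append(island_haps[idx])
            else:
                k = rng.poisson(config.mt_theta / 2.0)
                sequences.append("".join(mutate(list(ancestral), k)))
    return HaplotypeAlignment(sample_ids, sequences, regions)


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    mtdna: HaplotypeAlignment
    frequencies: pd.DataFrame
    config: SimulationConfig


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run the full generator: frequencies, genotypes, quality model, mtDNA."""
    config = config or SimulationConfig()
    freqs = simulate_allele_frequencies(config)
    g, meta = simulate_genotypes(freqs, config)
    g = apply_quality_model(g, meta, config)
    mt = simulate_mtdna(config)
    return SimulatedStudy(g, meta, mt, freqs, config)
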