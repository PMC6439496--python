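"""Central data containers for the two-step goshawk population-genomics pipeline.

The pipeline operates on diploid biallelic SNP genotypes stored as ALT-allele
dosages (0, 1, 2, or missing) with per-genotype qualities, plus aligned mtDNA
control-region sequences.  Coordinates are 1-based as in VCF; every internal
interval is half-open ``[start, stop)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for a missing dosage in integer genotype arrays.
MISSING = -1

#: Region codes used in sample metadata.
REGIONS = frozenset(
    {"HG", "AA", "AK", "BC", "BCc", "East", "VI", "WA", "Eur", "outgroup"}
)

#: DNA source tiers, ordered roughly by expected DNA quality.
SOURCES = frozenset({"tissue", "blood", "feather", "toepad"})

SEXES = frozenset({"M", "F", "unknown"})

_BASES = frozenset("ACGT")


def span_bp(start: int, stop: int) -> int:
    """Length in bp of the half-open segment ``[start, stop)``.

    Primer-delimited segments quoted as "between positions a and b" follow
    this convention: the control region between positions 1,169 and 1,747
    spans 578 bp.
    """
    if stop < start:
        raise ValueError(f"stop {stop} precedes start {start}")
    return stop - start


@dataclass(frozen=True)
class SiteRecord:
    """One variant site: scaffold, 1-based position, alleles, optional flanks."""

    scaffold: str
    position: int
    ref: str = "A"
    alt: str = "C"
    flank_left: str = ""
    flank_right: str = ""
    is_snp: bool = True
    is_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.is_snp and self.is_biallelic:
            if self.ref == self.alt:
                raise ValueError("ref and alt alleles must differ")
            if self.ref not in _BASES or self.alt not in _BASES:
                raise ValueError(
                    f"SNP alleles must be in ACGT: {self.ref}/{self.alt}"
                )


@dataclass(frozen=True)
class SampleRecord:
    """Sample metadata: region of origin, DNA source tier, and sex."""

    sample_id: str
    region: str
    source: str = "tissue"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region code {self.region!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")


class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with per-genotype quality.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers.
    sites
        Ordered :class:`SiteRecord` list.
    dosage
        Integer array (samples x sites) of ALT-allele counts; ``MISSING``
        (-1) marks a missing genotype.
    quality
        Float array of the same shape; ``nan`` where quality is unknown.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        sites: Sequence[SiteRecord],
        dosage: np.ndarray,
        quality: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.sites = list(sites)
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        valid = (dosage == MISSING) | ((dosage >= 0) & (dosage <= 2))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (-1)")
        self.dosage = dosage
        if quality is None:
            quality = np.full(dosage.shape, np.nan)
        quality = np.asarray(quality, dtype=float)
        if quality.shape != dosage.shape:
            raise ValueError("quality shape must match dosage shape")
        self.quality = quality

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.sites),
            self.dosage.copy(),
            self.quality.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites == other.sites
            and np.array_equal(self.dosage, other.dosage)
            and np.allclose(self.quality, other.quality, equal_nan=True)
        )

    # -- subsetting --------------------------------------------------------

    def take_sites(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.sites[i] for i in idx],
            self.dosage[:, idx],
            self.quality[:, idx],
        )

    def take_samples(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.sites),
            self.dosage[idx, :],
            self.quality[idx, :],
        )

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices of the given sample ids, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.asarray([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    # -- per-site summaries ------------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    def alt_allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing genotypes.

        Returns ``nan`` at sites with no calls among the selected rows.
        """
        d = self.dosage if rows is None else self.dosage[rows]
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_allele_freq(rows)
        return np.minimum(p, 1.0 - p)

    def site_missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)


class HaplotypeAlignment:
    """Equal-length aligned mtDNA sequences keyed by sample id."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        sequences: Sequence[str],
        regions: dict[str, str] | None = None,
    ) -> None:
        if len(sample_ids) != len(sequences):
            raise ValueError("one sequence per sample id required")
        sequences = [s.upper() for s in sequences]
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if sequences and len(sequences[0]) == 0:
            raise ValueError("alignment length must be positive")
        self.sample_ids = list(sample_ids)
        self.sequences = sequences
        self.regions = dict(regions) if regions else {}

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def trim(self, start: int, stop: int) -> "HaplotypeAlignment":
        """Restrict to the half-open column interval ``[start, stop)`` (0-based)."""
        if not (0 <= start < stop <= self.length):
            raise ValueError(f"invalid trim interval [{start}, {stop})")
        return HaplotypeAlignment(
            list(self.sample_ids),
            [s[start:stop] for s in self.sequences],
            self.regions,
        )

    def to_int_array(self) -> np.ndarray:
        """Encode as an int array: A,C,G,T -> 0..3, anything else -> -1."""
        table = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate("ACGT"):
            table[ord(b)] = i
        out = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, s in enumerate(self.sequences):
            out[i] = table[np.frombuffer(s.encode(), dtype=np.uint8)]
        return out
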