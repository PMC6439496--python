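"""Readers and writers for VCF, FASTA alignments, and sample-metadata TSV.

VCF reading goes through cyvcf2/htslib; writing emits minimal VCF v4.2 text
directly so output is byte-stable across runs.  All readers accept gzipped
input transparently (by extension).
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import MISSING, GenotypeMatrix, HaplotypeAlignment, SampleRecord, SiteRecord


class VcfParseError(ValueError):
    pass


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Biallelic SNP rows become ALT-allele dosages; missing genotypes become
    ``MISSING``; absent GQ becomes ``nan``.  Indel and multiallelic rows are
    retained but flagged (``is_snp`` / ``is_biallelic``) so the biallelic
    filter can drop them downstream.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    sites: list[SiteRecord] = []
    dosage_rows: list[np.ndarray] = []
    qual_rows: list[np.ndarray] = []
    for lineno, var in enumerate(vcf, start=1):
        try:
            alts = var.ALT
            is_biallelic = len(alts) == 1
            is_snp = (
                len(var.REF) == 1
                and all(len(a) == 1 for a in alts)
                and var.REF in "ACGT"
                and all(a in "ACGT" for a in alts)
                and len(alts) >= 1
            )
            alt = alts[0] if alts else "."
            d = np.asarray(var.gt_types, dtype=np.int16)  # 0,1,2 dosage; 3 unknown
            d[d == 3] = MISSING
            try:
                gq = var.format("GQ")
            except KeyError:  # GQ absent from the header entirely
                gq = None
            if gq is None:
                q = np.full(len(sample_ids), np.nan)
            else:
                q = np.asarray(gq, dtype=float).reshape(len(sample_ids))
                q[q < 0] = np.nan
            q[d == MISSING] = np.nan
            sites.append(
                SiteRecord(
                    scaffold=var.CHROM,
                    position=var.POS,
                    ref=var.REF if is_snp and is_biallelic else "A",
                    alt=alt if is_snp and is_biallelic else "C",
                    flank_left=var.INFO.get("FL") or "",
                    flank_right=var.INFO.get("FR") or "",
                    is_snp=is_snp,
                    is_biallelic=is_biallelic,
                )
            )
            dosage_rows.append(d)
            qual_rows.append(q)
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record #{lineno} in {path}: {exc}"
            ) from exc
    if not sites:
        return GenotypeMatrix(sample_ids, [], np.zeros((len(sample_ids), 0), dtype=np.int16))
    dosage = np.stack(dosage_rows, axis=1)
    quality = np.stack(qual_rows, axis=1)
    return GenotypeMatrix(sample_ids, sites, dosage, quality)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT and GQ, sorted by (scaffold, position)."""
    order = sorted(range(g.n_sites), key=lambda i: (g.sites[i].scaffold, g.sites[i].position))
    keys = [(g.sites[i].scaffold, g.sites[i].position) for i in order]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (scaffold, position) pairs: {dupes[:5]}")
    contigs = sorted({g.sites[i].scaffold for i in order})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=FL,Number=1,Type=String,Description="Left flanking sequence">',
        '##INFO=<ID=FR,Number=1,Type=String,Description="Right flanking sequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids),
    ]
    for j in order:
        site = g.sites[j]
        info = "."
        if site.flank_left or site.flank_right:
            info = f"FL={site.flank_left};FR={site.flank_right}"
        fields = [site.scaffold, str(site.position), ".", site.ref, site.alt, ".", ".", info, "GT:GQ"]
        for i in range(g.n_samples):
            gt = _GT_STRINGS[int(g.dosage[i, j])]
            q = g.quality[i, j]
            fields.append(f"{gt}:{int(round(q))}" if np.isfinite(q) else f"{gt}:.")
        lines.append("\t".join(fields))
    text = "\n".join(lines) + "\n"
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# FASTA alignment
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA; sequences are uppercased and length-checked."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return HaplotypeAlignment(
        [r.id for r in records], [str(r.seq).upper() for r in records]
    )


def write_fasta_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    buf = _io.StringIO()
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        buf.write(f">{sid}\n{seq}\n")
    path = str(path)
    opener = gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")
    with opener as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "region", "source", "sex"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, region, source, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    # validate codes eagerly via SampleRecord
    for row in df.itertuples(index=False):
        SampleRecord(row.sample_id, row.region, row.source, row.sex)
    return df[METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def metadata_records(meta: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(r.sample_id, r.region, r.source, r.sex)
        for r in meta.itertuples(index=False)
    ]


def region_indices(g: GenotypeMatrix, meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map region code -> row indices of the matrix, using the metadata table."""
    by_sample = dict(zip(meta["sample_id"], meta["region"]))
    out: dict[str, list[int]] = {}
    for i, sid in enumerate(g.sample_ids):
        region = by_sample.get(sid)
        if region is not None:
            out.setdefault(region, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}
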