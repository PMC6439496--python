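"""mtDNA haplotype analyses: p-distances, NJ tree, collapsing, MST network.

The haplotype network is a minimum spanning tree over Hamming distances
between observed haplotypes - a deliberate substitute for median-joining
network inference, which additionally infers unobserved intermediate
haplotypes.  Sequences differing only at an N are treated as distinct
haplotypes (N is not a wildcard), a conservative choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import HaplotypeAlignment


def p_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Uncorrected pairwise p-distances with pairwise deletion of N/gaps."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    enc = aln.to_int_array()
    n = aln.n_sequences
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(valid.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.sample_ids[i]} and "
                    f"{aln.sample_ids[j]}"
                )
            dist[i, j] = dist[j, i] = float((enc[i, valid] != enc[j, valid]).sum() / m)
    return dist


def neighbor_joining(dist: np.ndarray, ids: list[str]) -> str:
    """Neighbor-Joining tree (Saitou & Nei) as a newick string.

    Negative branch lengths are clamped to zero.  NJ recovers the
    generating tree exactly on additive distance matrices.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    dist = (dist + dist.T) / 2.0  # absorb float round-off
    tree = nj(DistanceMatrix(dist, ids), neg_as_zero=True)
    return str(tree).strip()


class HaplotypeTable:
    """Collapsed haplotypes with frequencies and per-region breakdown."""

    def __init__(self, haplotypes: list[str], members: list[list[str]],
                 region_counts: list[dict[str, int]]) -> None:
        self.haplotypes = haplotypes
        self.members = members
        self.region_counts = region_counts
        self.labels = [f"H{i + 1}" for i in range(len(haplotypes))]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def frequencies(self) -> list[int]:
        return [len(m) for m in self.members]

    def to_frame(self) -> pd.DataFrame:
        regions = sorted({r for rc in self.region_counts for r in rc})
        rows = []
        for lab, hap, mem, rc in zip(
            self.labels, self.haplotypes, self.members, self.region_counts
        ):
            row = {"haplotype": lab, "n": len(mem), "sequence": hap}
            for r in regions:
                row[r] = rc.get(r, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def collapse_haplotypes(
    aln: HaplotypeAlignment,
    regions: dict[str, str] | None = None,
    trim: tuple[int, int] | None = None,
) -> HaplotypeTable:
    """Group identical sequences into haplotypes with per-region counts.

    ``trim`` restricts to a half-open 0-based column interval first (the
    common well-covered stretch of the alignment).  Haplotypes are ordered
    by decreasing frequency, ties by sequence.
    """
    if trim is not None:
        aln = aln.trim(*trim)
    regions = regions if regions is not None else aln.regions
    groups: dict[str, list[str]] = {}
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        groups.setdefault(seq, []).append(sid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haps, members, rcounts = [], [], []
    for seq, mem in ordered:
        haps.append(seq)
        members.append(mem)
        rc: dict[str, int] = {}
        for sid in mem:
            r = regions.get(sid, "unknown")
            rc[r] = rc.get(r, 0) + 1
        rcounts.append(rc)
    return HaplotypeTable(haps, members, rcounts)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mst_haplotype_network(table: HaplotypeTable) -> list[tuple[str, str, int]]:
    """Minimum spanning tree over haplotype Hamming distances.

    Kruskal with edges sorted by (weight, label pair) for a fully
    deterministic result; returns (label_a, label_b, steps) edges.
    """
    n = table.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    edges = sorted(
        (
            _hamming(table.haplotypes[i], table.haplotypes[j]),
            table.labels[i],
            table.labels[j],
        )
        for i in range(n)
        for j in range(i + 1, n)
    )
    parent = {lab: lab for lab in table.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b, w))
        if len(out) == n - 1:
            break
    return out
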