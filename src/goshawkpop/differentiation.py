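"""Differentiation and divergence statistics.

Implements the diploid two-population Weir & Cockerham (1984) variance-
components F_ST estimator (weighted estimate = sum(a) / sum(a+b+c), never a
mean of per-site ratios), Hudson's sequence-based F_ST (1 - Hw/Hb), windowed
D_XY / D_X / D_Y over callsets that retain invariant sites, net divergence
D_A = D_XY - 0.5 (D_X + D_Y) and its conversion to a divergence time via
D = 2 mu t, TN93 distances with gamma rate variation for mtDNA, and the
method-of-moments per-individual inbreeding coefficient F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, HaplotypeAlignment


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_fst(
    g: GenotypeMatrix, group1: np.ndarray, group2: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Per-site Weir-Cockerham variance components and the weighted F_ST.

    A site contributes only if each group has >= 2 non-missing genotypes
    there.  Per-site ratios a/(a+b+c) are reported for outlier screens and
    are NaN where a+b+c <= 0; the weighted estimate uses component sums and
    may be negative (it is not clamped).
    """
    group1 = np.asarray(group1, dtype=int)
    group2 = np.asarray(group2, dtype=int)
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")

    d = g.dosage
    comp = np.zeros((g.n_sites, 3))
    usable = np.zeros(g.n_sites, dtype=bool)

    def _group_stats(rows):
        sub = d[rows]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)                 # individuals
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(
                n > 0,
                ((sub == 1) & called).sum(axis=0) / np.maximum(n, 1),
                np.nan,
            )
        return n, p, h

    n1, p1, h1 = _group_stats(group1)
    n2, p2, h2 = _group_stats(group2)
    usable = (n1 >= 2) & (n2 >= 2)

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    comp[:, 0] = np.where(usable, a, np.nan)
    comp[:, 1] = np.where(usable, b, np.nan)
    comp[:, 2] = np.where(usable, c, np.nan)
    denom = comp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, comp[:, 0] / denom, np.nan)

    table = pd.DataFrame(
        {
            "scaffold": [s.scaffold for s in g.sites],
            "position": [s.position for s in g.sites],
            "a": comp[:, 0],
            "b": comp[:, 1],
            "c": comp[:, 2],
            "ratio": ratio,
        }
    )
    sum_a = np.nansum(comp[usable, 0])
    sum_abc = np.nansum(denom[usable])
    if sum_abc == 0:
        raise ValueError("no usable sites for weighted F_ST")
    return table, float(sum_a / sum_abc)


def fst_outlier_threshold(ratios: np.ndarray, q: float = 0.99) -> float:
    """Empirical q-quantile of defined per-site F_ST ratios.

    Linear interpolation between order statistics; sites at or above the
    returned value form the outlier tail.
    """
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) == 0:
        raise ValueError("no defined F_ST ratios")
    return float(np.quantile(ratios, q, method="linear"))


# ---------------------------------------------------------------------------
# Hudson sequence-based F_ST
# ---------------------------------------------------------------------------

def _pairwise_diff_rates(enc: np.ndarray, rows_a, rows_b, within: bool) -> list[float]:
    rates = []
    for ai, i in enumerate(rows_a):
        js = rows_b[ai + 1:] if within else rows_b
        for j in js:
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            n = int(valid.sum())
            if n == 0:
                continue
            rates.append(float((enc[i, valid] != enc[j, valid]).sum() / n))
    return rates


def hudson_fst(aln: HaplotypeAlignment, group1: list[str], group2: list[str]) -> float:
    """Hudson, Slatkin & Maddison F_ST = 1 - Hw/Hb on aligned sequences.

    Hw is the unweighted mean of the two within-group mean pairwise
    difference rates and Hb the between-group mean rate, with pairwise
    deletion of sites where either sequence has N or a gap.  May be
    negative when within-group diversity exceeds between-group.
    """
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    rows1 = [idx[s] for s in group1]
    rows2 = [idx[s] for s in group2]
    if len(rows1) < 2 or len(rows2) < 2:
        raise ValueError("each group needs >= 2 sequences")
    enc = aln.to_int_array()
    hw1 = _pairwise_diff_rates(enc, rows1, rows1, within=True)
    hw2 = _pairwise_diff_rates(enc, rows2, rows2, within=True)
    hb = _pairwise_diff_rates(enc, rows1, rows2, within=False)
    Hw = 0.5 * (float(np.mean(hw1)) + float(np.mean(hw2)))
    Hb = float(np.mean(hb))
    if Hb == 0:
        raise ValueError("between-group diversity is zero; Hudson F_ST undefined")
    return 1.0 - Hw / Hb


# ---------------------------------------------------------------------------
# Windowed divergence
# ---------------------------------------------------------------------------

@dataclass
class WindowDivergence:
    """Per-window average pairwise difference rates (1-based, half-open)."""

    scaffold: str
    start: int
    end: int
    n_sequenced_bp: int
    DXY: float
    DX: float
    DY: float


def _site_divergence(g: GenotypeMatrix, rows: np.ndarray):
    """Allele frequency, allele count, and unbiased within-group pi per site."""
    sub = g.dosage[rows]
    called = sub != MISSING
    n_allele = (2 * called.sum(axis=0)).astype(float)
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_allele > 0, alt / np.maximum(n_allele, 1), np.nan)
        pi = np.where(
            n_allele > 1,
            2.0 * p * (1.0 - p) * n_allele / np.maximum(n_allele - 1.0, 1.0),
            np.nan,
        )
    return p, n_allele, pi


def windowed_divergence(
    g: GenotypeMatrix,
    groupX: np.ndarray,
    groupY: np.ndarray,
    window_bp_sequenced: int = 5000,
    max_missing: float = 0.60,
) -> list[WindowDivergence]:
    """D_XY, D_X, D_Y in windows of a fixed number of sequenced positions.

    The callset must retain invariant sites so that per-site rates average
    correctly.  Sites with overall missingness > ``max_missing`` are
    excluded; windows accumulate the next ``window_bp_sequenced`` retained
    positions per scaffold.  A terminal window is kept only if it holds at
    least half the target positions.  D_XY per site is the between-group
    average pairwise difference probability p_x(1-p_y) + p_y(1-p_x); D_X
    and D_Y use the sample-size-unbiased within-group form.
    """
    groupX = np.asarray(groupX, dtype=int)
    groupY = np.asarray(groupY, dtype=int)
    rows_all = np.concatenate([groupX, groupY])
    miss = (g.dosage[rows_all] == MISSING).mean(axis=0)
    pX, nX, piX = _site_divergence(g, groupX)
    pY, nY, piY = _site_divergence(g, groupY)
    retained = (miss <= max_missing) & (nX > 1) & (nY > 1)

    dxy = pX * (1.0 - pY) + pY * (1.0 - pX)

    windows: list[WindowDivergence] = []
    order = sorted(
        np.flatnonzero(retained),
        key=lambda j: (g.sites[j].scaffold, g.sites[j].position),
    )
    by_scaffold: dict[str, list[int]] = {}
    for j in order:
        by_scaffold.setdefault(g.sites[j].scaffold, []).append(j)
    half = window_bp_sequenced // 2
    for scaffold, sites in by_scaffold.items():
        for w0 in range(0, len(sites), window_bp_sequenced):
            block = sites[w0:w0 + window_bp_sequenced]
            if len(block) < window_bp_sequenced and len(block) < half:
                continue
            idx = np.asarray(block)
            windows.append(
                WindowDivergence(
                    scaffold=scaffold,
                    start=g.sites[block[0]].position,
                    end=g.sites[block[-1]].position + 1,
                    n_sequenced_bp=len(block),
                    DXY=float(np.mean(dxy[idx])),
                    DX=float(np.mean(piX[idx])),
                    DY=float(np.mean(piY[idx])),
                )
            )
    return windows


def genome_divergence(windows: list[WindowDivergence]) -> tuple[float, float, float]:
    """Unweighted mean of D_XY, D_X, D_Y over windows."""
    if not windows:
        raise ValueError("no windows")
    return (
        float(np.mean([w.DXY for w in windows])),
        float(np.mean([w.DX for w in windows])),
        float(np.mean([w.DY for w in windows])),
    )


def net_divergence(DXY: float, DX: float, DY: float) -> float:
    """Net divergence D_A = D_XY - 0.5 (D_X + D_Y)."""
    return DXY - 0.5 * (DX + DY)


@dataclass
class DivergenceEstimate:
    DA: float
    mu: float
    t_years: float | None

    @property
    def estimable(self) -> bool:
        return self.t_years is not None


def divergence_time(DA: float, mu: float) -> DivergenceEstimate:
    """Divergence time t = D_A / (2 mu) under the neutral expectation D = 2 mu t.

    Negative D_A (shared variation exceeding divergence) is flagged
    non-estimable rather than reported as a negative time.
    """
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    if DA < 0:
        return DivergenceEstimate(DA, mu, None)
    return DivergenceEstimate(DA, mu, DA / (2.0 * mu))


# ---------------------------------------------------------------------------
# TN93 + gamma distances (mtDNA)
# ---------------------------------------------------------------------------

_PURINES = (0, 2)   # A, G in the ACGT encoding
_PYRIMIDINES = (1, 3)  # C, T


def tn93_gamma_distance(
    aln: HaplotypeAlignment, gamma_shape: float = 0.05
) -> np.ndarray:
    """Pairwise Tamura-Nei (1993) distances with gamma rate variation.

    Base frequencies are estimated from each sequence pair jointly
    (pairwise deletion of non-ACGT columns).  Saturated pairs, where the
    correction's argument becomes non-positive, get NaN with a warning.
    """
    enc = aln.to_int_array()
    n = aln.n_sequences
    dist = np.zeros((n, n))
    a = gamma_shape
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            L = int(valid.sum())
            if L == 0:
                raise ValueError(
                    f"no comparable sites between {aln.sample_ids[i]} and "
                    f"{aln.sample_ids[j]}"
                )
            si, sj = enc[i, valid], enc[j, valid]
            counts = np.bincount(np.concatenate([si, sj]), minlength=4) / (2.0 * L)
            pA, pC, pG, pT = counts
            pR, pY = pA + pG, pC + pT
            diff = si != sj
            both = si * 4 + sj
            P1 = float(np.mean(diff & np.isin(both, [0 * 4 + 2, 2 * 4 + 0])))  # A<->G
            P2 = float(np.mean(diff & np.isin(both, [1 * 4 + 3, 3 * 4 + 1])))  # C<->T
            Q = float(np.mean(diff)) - P1 - P2
            k1 = 2.0 * pA * pG / pR if pR > 0 else 0.0
            k2 = 2.0 * pT * pC / pY if pY > 0 else 0.0
            k3 = 2.0 * (
                pR * pY
                - (pA * pG * pY / pR if pR > 0 else 0.0)
                - (pT * pC * pR / pY if pY > 0 else 0.0)
            )
            w1 = 1.0 - P1 / k1 - Q / (2.0 * pR) if k1 > 0 else 1.0
            w2 = 1.0 - P2 / k2 - Q / (2.0 * pY) if k2 > 0 else 1.0
            w3 = 1.0 - Q / (2.0 * pR * pY) if pR * pY > 0 else 1.0
            if min(w1, w2, w3) <= 0:
                warnings.warn(
                    f"saturated pair {aln.sample_ids[i]}/{aln.sample_ids[j]}; "
                    "TN93 distance undefined"
                )
                dist[i, j] = dist[j, i] = np.nan
                continue
            d = a * (
                k1 * (w1 ** (-1.0 / a) - 1.0)
                + k2 * (w2 ** (-1.0 / a) - 1.0)
                + k3 * (w3 ** (-1.0 / a) - 1.0)
            )
            dist[i, j] = dist[j, i] = max(d, 0.0)
    return dist


def mtdna_net_divergence(
    aln: HaplotypeAlignment, group1: list[str], group2: list[str],
    gamma_shape: float = 0.05,
) -> float:
    """D_A for mtDNA from mean within/between TN93+gamma distances."""
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    rows1 = [idx[s] for s in group1]
    rows2 = [idx[s] for s in group2]
    dist = tn93_gamma_distance(aln, gamma_shape)

    def _mean_within(rows):
        vals = [dist[i, j] for ai, i in enumerate(rows) for j in rows[ai + 1:]]
        return float(np.nanmean(vals))

    dxy = float(np.nanmean([dist[i, j] for i in rows1 for j in rows2]))
    return net_divergence(dxy, _mean_within(rows1), _mean_within(rows2))


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def inbreeding_F(g: GenotypeMatrix, group: np.ndarray) -> pd.Series:
    """Method-of-moments inbreeding coefficient per sample within a group.

    F = (O_hom - E_hom) / (L - E_hom), with E_hom summed over the sample's
    non-missing sites as 1 - 2 p (1-p) 2n/(2n-1), where p and the allele
    count 2n come from the group's genotypes at each site.  Values may be
    negative (heterozygote excess); a degenerate denominator gives NaN.
    """
    group = np.asarray(group, dtype=int)
    sub = g.dosage[group]
    called = sub != MISSING
    n_allele = (2 * called.sum(axis=0)).astype(float)
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_allele > 0, alt / np.maximum(n_allele, 1), np.nan)
        e_hom_site = np.where(
            n_allele > 1,
            1.0 - 2.0 * p * (1.0 - p) * n_allele / np.maximum(n_allele - 1.0, 1.0),
            np.nan,
        )
    out = {}
    for k, i in enumerate(group):
        use = called[k] & np.isfinite(e_hom_site)
        L = int(use.sum())
        o_hom = int(((sub[k] == 0) | (sub[k] == 2))[use].sum())
        e_hom = float(e_hom_site[use].sum())
        denom = L - e_hom
        out[g.sample_ids[i]] = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
    return pd.Series(out, name="F")
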