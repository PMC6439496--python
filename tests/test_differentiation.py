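"""Differentiation estimators against brute-force oracles and closed forms."""

import numpy as np
import pytest

from goshawkpop.core import MISSING, HaplotypeAlignment
from goshawkpop.differentiation import (
    divergence_time,
    fst_outlier_threshold,
    genome_divergence,
    hudson_fst,
    inbreeding_F,
    mtdna_net_divergence,
    net_divergence,
    tn93_gamma_distance,
    wc_fst,
    windowed_divergence,
)
from goshawkpop.simulate import (
    SimulationConfig,
    simulate_allele_frequencies,
    simulate_genotypes,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Weir-Cockerham oracle: independent scalar transcription of the 1984
# two-level variance components for one site.
# ---------------------------------------------------------------------------

def _wc_site_oracle(d1, d2):
    d1 = [x for x in d1 if x != MISSING]
    d2 = [x for x in d2 if x != MISSING]
    n1, n2 = len(d1), len(d2)
    p1 = sum(d1) / (2 * n1)
    p2 = sum(d2) / (2 * n2)
    h1 = sum(1 for x in d1 if x == 1) / n1
    h2 = sum(1 for x in d2 if x == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def test_wc_fst_matches_site_oracle_on_random_fixture():
    rng = np.random.default_rng(42)
    d = rng.integers(0, 3, size=(10, 6)).astype(np.int16)
    d[0, 0] = MISSING
    d[7, 3] = MISSING
    g = make_matrix(d)
    g1, g2 = np.arange(5), np.arange(5, 10)
    table, weighted = wc_fst(g, g1, g2)
    sum_a = sum_abc = 0.0
    for j in range(6):
        a, b, c = _wc_site_oracle(d[:5, j], d[5:, j])
        assert table["a"][j] == pytest.approx(a, abs=1e-12)
        assert table["b"][j] == pytest.approx(b, abs=1e-12)
        assert table["c"][j] == pytest.approx(c, abs=1e-12)
        sum_a += a
        sum_abc += a + b + c
    assert weighted == pytest.approx(sum_a / sum_abc, abs=1e-12)


def test_wc_fst_is_one_for_fixed_difference():
    d = np.array([[0] * 4] * 10 + [[2] * 4] * 10)
    g = make_matrix(d)
    _, weighted = wc_fst(g, np.arange(10), np.arange(10, 20))
    assert weighted == pytest.approx(1.0, abs=1e-12)


def test_wc_fst_nonpositive_for_identical_groups():
    rng = np.random.default_rng(1)
    block = rng.integers(0, 3, size=(8, 50))
    g = make_matrix(np.vstack([block, block]))
    _, weighted = wc_fst(g, np.arange(8), np.arange(8, 16))
    assert weighted <= 1e-12  # estimator may go negative; never clamped


def test_wc_fst_recovers_drift_parameter():
    cfg = SimulationConfig(
        n_sites=5000,
        region_sizes={"HG": 12, "East": 107},
        drift_F={"HG": 0.08, "East": 0.08},
        source_tiers={"HG": {"tissue": 1.0}, "East": {"tissue": 1.0}},
        seed=17,
    )
    g, meta = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
    island = np.flatnonzero(meta["region"] == "HG")
    rest = np.flatnonzero(meta["region"] != "HG")
    _, weighted = wc_fst(g, island, rest)
    assert weighted == pytest.approx(0.08, abs=0.02)


def test_outlier_threshold_quantile_convention():
    ratios = np.arange(100) / 100.0
    thr = fst_outlier_threshold(ratios, q=0.99)
    assert 0.98 <= thr <= 0.99
    assert fst_outlier_threshold(np.full(20, 0.4)) == pytest.approx(0.4)
    # flagged set monotone in q
    t90 = fst_outlier_threshold(ratios, q=0.90)
    assert (ratios >= thr).sum() <= (ratios >= t90).sum()
    with pytest.raises(ValueError):
        fst_outlier_threshold(np.array([np.nan]))


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def _pairwise_rate_oracle(seqs_a, seqs_b, within):
    rates = []
    for i, a in enumerate(seqs_a):
        others = seqs_b[i + 1:] if within else seqs_b
        for b in others:
            valid = [
                (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
            ]
            rates.append(sum(x != y for x, y in valid) / len(valid))
    return rates


def test_hudson_fst_matches_hand_computed_fixture():
    seqs1 = ["ACGTACGT", "ACGTACGA"]
    seqs2 = ["TCGTACGG", "TCGAACGG"]
    aln = HaplotypeAlignment(["a1", "a2", "b1", "b2"], seqs1 + seqs2)
    hw = 0.5 * (
        np.mean(_pairwise_rate_oracle(seqs1, seqs1, True))
        + np.mean(_pairwise_rate_oracle(seqs2, seqs2, True))
    )
    hb = np.mean(_pairwise_rate_oracle(seqs1, seqs2, False))
    expected = 1 - hw / hb
    got = hudson_fst(aln, ["a1", "a2"], ["b1", "b2"])
    assert got == pytest.approx(expected, abs=1e-12)


def test_hudson_fst_one_when_groups_internally_identical():
    aln = HaplotypeAlignment(
        ["a1", "a2", "b1", "b2"], ["AAAA", "AAAA", "TTTT", "TTTT"]
    )
    assert hudson_fst(aln, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(1.0)


def test_hudson_fst_near_zero_for_one_pool():
    rng = np.random.default_rng(5)
    pool = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
    seqs = [pool[int(rng.integers(4))] for _ in range(12)]
    ids = [f"s{i}" for i in range(12)]
    aln = HaplotypeAlignment(ids, seqs)
    f = hudson_fst(aln, ids[:6], ids[6:])
    assert abs(f) < 0.15  # may be slightly negative


def test_hudson_fst_undefined_without_between_diversity():
    aln = HaplotypeAlignment(["a", "b", "c", "d"], ["AAAA"] * 4)
    with pytest.raises(ValueError, match="undefined"):
        hudson_fst(aln, ["a", "b"], ["c", "d"])


# ---------------------------------------------------------------------------
# Windowed divergence
# ---------------------------------------------------------------------------

def _allele_pool(ds):
    pool = []
    for d in ds:
        if d != MISSING:
            pool += [1] * d + [0] * (2 - d)
    return pool


def _site_dxy_oracle(d1, d2):
    p1, p2 = _allele_pool(d1), _allele_pool(d2)
    between = [int(x != y) for x in p1 for y in p2]
    within1 = [
        int(p1[i] != p1[j]) for i in range(len(p1)) for j in range(i + 1, len(p1))
    ]
    within2 = [
        int(p2[i] != p2[j]) for i in range(len(p2)) for j in range(i + 1, len(p2))
    ]
    return np.mean(between), np.mean(within1), np.mean(within2)


def test_windowed_divergence_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(9)
    d = rng.integers(0, 3, size=(8, 12)).astype(np.int16)
    d[2, 5] = MISSING
    g = make_matrix(d)
    gX, gY = np.arange(4), np.arange(4, 8)
    windows = windowed_divergence(g, gX, gY, window_bp_sequenced=12)
    assert len(windows) == 1
    oracle = np.array([_site_dxy_oracle(d[:4, j], d[4:, j]) for j in range(12)])
    w = windows[0]
    assert w.DXY == pytest.approx(oracle[:, 0].mean(), abs=1e-10)
    assert w.DX == pytest.approx(oracle[:, 1].mean(), abs=1e-10)
    assert w.DY == pytest.approx(oracle[:, 2].mean(), abs=1e-10)
    assert w.n_sequenced_bp == 12


def test_windowed_divergence_trivial_cases():
    mono = make_matrix(np.zeros((8, 10), dtype=int))
    w = windowed_divergence(mono, np.arange(4), np.arange(4, 8), 10)
    assert w[0].DXY == 0 and w[0].DX == 0 and w[0].DY == 0

    fixed = make_matrix(np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(int))
    w = windowed_divergence(fixed, np.arange(4), np.arange(4, 8), 10)
    assert w[0].DXY == pytest.approx(1.0)
    assert w[0].DX == 0 and w[0].DY == 0


def test_window_missingness_and_terminal_window_rules():
    d = np.zeros((10, 25), dtype=int)
    d[:, 0] = [2] * 5 + [0] * 5
    # site 1: 7/10 missing (> 0.60) -> excluded entirely
    d[:7, 1] = MISSING
    g = make_matrix(d)
    windows = windowed_divergence(g, np.arange(5), np.arange(5, 10), 10)
    # 24 retained sites -> one full 10-site window + one of 10 + terminal 4 < 5 dropped
    assert [w.n_sequenced_bp for w in windows] == [10, 10]
    DXY, DX, DY = genome_divergence(windows)
    assert DXY == pytest.approx(np.mean([w.DXY for w in windows]))


def test_net_divergence_arithmetic():
    assert net_divergence(0.0, 0.0, 0.0) == 0.0
    assert net_divergence(0.01, 0.01, 0.01) == pytest.approx(0.0)
    assert net_divergence(0.012, 0.008, 0.006) == pytest.approx(0.005)


# ---------------------------------------------------------------------------
# TN93 + gamma and divergence time
# ---------------------------------------------------------------------------

def test_tn93_zero_for_identical_and_symmetric():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list("ACGT"), size=200))
    # moderately diverged relative: 5% of positions substituted
    seq = list(base)
    for pos in rng.choice(200, size=10, replace=False):
        seq[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[pos]]
    aln = HaplotypeAlignment(["a", "b", "c"], [base, base, "".join(seq)])
    d = tn93_gamma_distance(aln)
    assert d[0, 1] == 0.0
    assert d[0, 2] > 0
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0)


def test_tn93_saturated_pair_reported_undefined():
    rng = np.random.default_rng(4)
    a = "".join(rng.choice(list("ACGT"), size=80))
    b = "".join(rng.choice(list("ACGT"), size=80))
    aln = HaplotypeAlignment(["a", "b"], [a, b])
    with pytest.warns(UserWarning, match="saturated"):
        d = tn93_gamma_distance(aln)
    assert np.isnan(d[0, 1])


def test_tn93_approaches_p_distance_at_low_divergence():
    base = "ACGT" * 100
    mutated = "CCGT" + base[4:]  # one difference in 400 bp
    aln = HaplotypeAlignment(["a", "b"], [base, mutated])
    d = tn93_gamma_distance(aln, gamma_shape=0.05)
    p = 1 / 400
    assert d[0, 1] == pytest.approx(p, rel=0.05)


def test_mtdna_net_divergence_matches_hand_computed_means():
    rng = np.random.default_rng(8)
    base = list("".join(rng.choice(list("ACGT"), size=300)))
    seqs = []
    for k in range(6):  # close relatives: a handful of substitutions each
        s = base.copy()
        for pos in rng.choice(300, size=3, replace=False):
            s[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[pos]]
        seqs.append("".join(s))
    ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
    aln = HaplotypeAlignment(ids, seqs)
    da = mtdna_net_divergence(aln, ids[:3], ids[3:])
    dist = tn93_gamma_distance(aln)
    dxy = np.mean([dist[i, j] for i in range(3) for j in range(3, 6)])
    dx = np.mean([dist[0, 1], dist[0, 2], dist[1, 2]])
    dy = np.mean([dist[3, 4], dist[3, 5], dist[4, 5]])
    assert da == pytest.approx(dxy - 0.5 * (dx + dy), abs=1e-12)


def test_mtdna_net_divergence_positive_for_distinct_monomorphic_groups():
    a = "ACGT" * 50
    b = "ACGA" * 50  # 50 substitutions apart
    aln = HaplotypeAlignment(
        ["a1", "a2", "a3", "b1", "b2", "b3"], [a, a, a, b, b, b]
    )
    da = mtdna_net_divergence(aln, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    assert da > 0.2  # all divergence is between groups, none within


def test_divergence_time_inversions():
    assert divergence_time(0.0, 1e-9).t_years == 0.0
    est_nuc = divergence_time(1.104e-4, 2.30e-9)
    assert est_nuc.t_years == pytest.approx(24_000, rel=1e-6)
    est_mt = divergence_time(7.54e-3, 2.9e-7)
    assert est_mt.t_years == pytest.approx(13_000, rel=1e-6)
    assert not divergence_time(-0.001, 1e-9).estimable
    with pytest.raises(ValueError):
        divergence_time(0.001, 0.0)


# ---------------------------------------------------------------------------
# Inbreeding F
# ---------------------------------------------------------------------------

def test_inbreeding_one_for_fully_homozygous_sample():
    rng = np.random.default_rng(11)
    d = rng.integers(0, 3, size=(20, 300)).astype(np.int16)
    d[0] = np.where(d[0] == 1, 0, d[0])  # make sample 0 fully homozygous
    g = make_matrix(d)
    F = inbreeding_F(g, np.arange(20))
    assert F.iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_inbreeding_near_zero_under_hwe():
    rng = np.random.default_rng(12)
    p = rng.uniform(0.1, 0.9, size=3000)
    d = rng.binomial(2, p, size=(40, 3000)).astype(np.int16)
    g = make_matrix(d)
    F = inbreeding_F(g, np.arange(40))
    assert abs(F.mean()) < 0.01
    assert (F < 0).any()  # individual estimates go negative


def test_inbreeding_recovers_planted_f():
    rng = np.random.default_rng(13)
    p = rng.uniform(0.2, 0.8, size=2000)
    f_true = 0.25
    n = 40
    a1 = rng.random((n, 2000)) < p
    copy = rng.random((n, 2000)) < f_true
    a2 = np.where(copy, a1, rng.random((n, 2000)) < p)
    d = (a1.astype(int) + a2.astype(int)).astype(np.int16)
    g = make_matrix(d)
    F = inbreeding_F(g, np.arange(n))
    assert F.mean() == pytest.approx(f_true, abs=0.03)
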