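"""(S, H) likelihood, grid+refine estimation, hybrid classes, panel admixture."""

import numpy as np
import pytest

from goshawkpop.ancestry import (
    AncestryModel,
    admixture_on_panel,
    classify_hybrids,
    estimate_SH,
    hi_loglik,
)
from goshawkpop.core import MISSING, SiteRecord
from goshawkpop.panel import AimPanel

from conftest import make_matrix


def _panel(p1, p2):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    sites = [SiteRecord("chr1", 100 * (j + 1), "A", "G") for j in range(len(p1))]
    return AimPanel(
        sites=sites,
        site_index=list(range(len(p1))),
        fst_rank=list(range(1, len(p1) + 1)),
        fst=[1.0] * len(p1),
        p_ref1=p1,
        p_ref2=p2,
    )


def _simulate_individual(rng, S, H, p1, p2, n):
    cls = rng.choice(3, size=n, p=[S - H / 2, H, 1 - S - H / 2])
    a1 = rng.random(n) < np.where(cls == 2, p2, p1)
    a2 = rng.random(n) < np.where(cls == 0, p1, p2)
    return (a1.astype(np.int16) + a2.astype(np.int16))


def _oracle_loglik(dosage, p1, p2, S, H):
    """Direct scalar transcription of the three-class mixture likelihood."""
    total = 0.0
    for d, a, b in zip(dosage, p1, p2):
        if d == MISSING:
            continue
        qa, qb = 1 - a, 1 - b
        if d == 2:
            terms = (a * a, a * b, b * b)
        elif d == 1:
            terms = (2 * a * qa, a * qb + qa * b, 2 * b * qb)
        else:
            terms = (qa * qa, qa * qb, qb * qb)
        lik = (S - H / 2) * terms[0] + H * terms[1] + (1 - S - H / 2) * terms[2]
        total += np.log(max(lik, 1e-300))
    return total


def test_per_locus_probabilities_normalize():
    rng = np.random.default_rng(0)
    p1 = rng.uniform(0, 1, size=30)
    p2 = rng.uniform(0, 1, size=30)
    panel = _panel(p1, p2)
    for S, H in [(0.3, 0.2), (0.5, 1.0), (1.0, 0.0), (0.75, 0.5)]:
        total = sum(
            np.exp(
                hi_loglik(np.full(1, d, dtype=np.int16), _panel(p1[:1], p2[:1]), S, H)
            )
            for d in (0, 1, 2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)
    assert hi_loglik(np.full(30, 1, dtype=np.int16), panel, 0.5, 1.0) <= 0


def test_hi_loglik_matches_oracle_transcription():
    rng = np.random.default_rng(1)
    p1 = rng.uniform(0.05, 0.95, size=25)
    p2 = rng.uniform(0.05, 0.95, size=25)
    dosage = rng.integers(0, 3, size=25).astype(np.int16)
    dosage[3] = MISSING
    panel = _panel(p1, p2)
    for S, H in [(0.2, 0.1), (0.6, 0.4), (0.5, 0.9)]:
        assert hi_loglik(dosage, panel, S, H) == pytest.approx(
            _oracle_loglik(dosage, p1, p2, S, H), abs=1e-12
        )


def test_infeasible_point_rejected():
    panel = _panel([1.0], [0.0])
    with pytest.raises(ValueError):
        hi_loglik(np.array([1], dtype=np.int16), panel, 0.9, 0.5)


def test_diagnostic_all_het_individual_maximized_at_f1_point():
    n = 20
    panel = _panel([1.0] * n, [0.0] * n)
    dosage = np.ones(n, dtype=np.int16)
    assert hi_loglik(dosage, panel, 0.5, 1.0) == pytest.approx(0.0, abs=1e-12)
    assert hi_loglik(dosage, panel, 0.5, 0.8) < -1e-3
    est = estimate_SH(dosage, panel, min_loci=7)
    assert (est.S, est.H) == pytest.approx((0.5, 1.0), abs=1e-6)


def test_pure_individual_estimated_at_corner():
    n = 20
    panel = _panel([1.0] * n, [0.0] * n)
    est = estimate_SH(np.full(n, 2, dtype=np.int16), panel, min_loci=7)
    assert (est.S, est.H) == pytest.approx((1.0, 0.0), abs=1e-6)
    assert est.n_loci_used == n


def test_estimate_skips_samples_below_locus_minimum():
    panel = _panel([1.0] * 10, [0.0] * 10)
    d = np.full(10, MISSING, dtype=np.int16)
    d[:5] = 2
    assert estimate_SH(d, panel, min_loci=7) is None


def test_grid_refine_matches_dense_grid_oracle():
    rng = np.random.default_rng(2)
    p1 = rng.uniform(0.7, 1.0, size=40)
    p2 = rng.uniform(0.0, 0.3, size=40)
    panel = _panel(p1, p2)
    dosage = _simulate_individual(rng, 0.6, 0.4, p1, p2, 40)
    est = estimate_SH(dosage, panel, grid_step=0.005)
    dense = estimate_SH(dosage, panel, grid_step=0.001, refine=False)
    assert est.S == pytest.approx(dense.S, abs=0.005)
    assert est.H == pytest.approx(dense.H, abs=0.005)
    assert est.logL >= dense.logL - 1e-9


@pytest.mark.parametrize("S,H,tol_S,tol_H", [
    (0.5, 1.0, 0.03, 0.06),
    (1.0, 0.0, 0.03, 0.06),
    (0.75, 0.5, 0.03, 0.06),
])
def test_parameter_recovery_on_informative_panels(S, H, tol_S, tol_H):
    """Mean (S, H) over replicates recovered on 500 loci with |p1-p2| = 0.8."""
    rng = np.random.default_rng(7)
    n_loci, n_ind = 500, 10
    p1 = np.full(n_loci, 0.9)
    p2 = np.full(n_loci, 0.1)
    panel = _panel(p1, p2)
    ests = []
    for _ in range(n_ind):
        d = _simulate_individual(rng, S, H, p1, p2, n_loci)
        ests.append(estimate_SH(d, panel, grid_step=0.01))
    S_hat = np.mean([e.S for e in ests])
    H_hat = np.mean([e.H for e in ests])
    assert S_hat == pytest.approx(S, abs=tol_S)
    assert H_hat == pytest.approx(H, abs=tol_H)
    for e in ests:  # estimates always in the feasible triangle
        assert e.H <= 2 * min(e.S, 1 - e.S) + 1e-9


def test_small_panel_recovery_within_loose_tolerance():
    rng = np.random.default_rng(8)
    p1 = np.full(10, 0.9)
    p2 = np.full(10, 0.1)
    panel = _panel(p1, p2)
    ests = [
        estimate_SH(_simulate_individual(rng, 0.75, 0.5, p1, p2, 10), panel)
        for _ in range(30)
    ]
    assert np.mean([e.S for e in ests]) == pytest.approx(0.75, abs=0.15)
    assert np.mean([e.H for e in ests]) == pytest.approx(0.5, abs=0.25)


def test_hybrid_class_boundaries_inclusive():
    labels, counts = classify_hybrids(np.array([0.5, 0.25, 0.249, 0.8, 0.0]))
    assert list(labels) == ["high", "intermediate", "low", "high", "low"]
    assert counts == {"high": 2, "intermediate": 1, "low": 2}


def test_f1_cohort_classified_high():
    rng = np.random.default_rng(9)
    p1 = np.full(50, 0.95)
    p2 = np.full(50, 0.05)
    panel = _panel(p1, p2)
    H_hats = [
        estimate_SH(_simulate_individual(rng, 0.5, 1.0, p1, p2, 50), panel).H
        for _ in range(10)
    ]
    labels, counts = classify_hybrids(np.asarray(H_hats))
    assert counts["high"] == 10


def test_ancestry_model_fits_matrix_and_reports_skips():
    rng = np.random.default_rng(10)
    n_loci = 12
    p1 = np.full(n_loci, 0.9)
    p2 = np.full(n_loci, 0.1)
    panel = _panel(p1, p2)
    rows = [
        _simulate_individual(rng, 1.0, 0.0, p1, p2, n_loci),
        _simulate_individual(rng, 0.0, 0.0, p1, p2, n_loci),
        np.full(n_loci, MISSING, dtype=np.int16),
    ]
    sites = panel.sites
    g = make_matrix(np.vstack(rows), sample_ids=["pure1", "pure2", "empty"], sites=sites)
    res = AncestryModel(g, panel, min_loci=7).fit()
    df = res.to_frame()
    assert res.skipped == ["empty"]
    assert set(df["sample_id"]) == {"pure1", "pure2"}
    assert df.set_index("sample_id").loc["pure1", "S"] > 0.8
    assert df.set_index("sample_id").loc["pure2", "S"] < 0.2
    assert "class" in df.columns
    assert isinstance(res.summary(), str)


def test_panel_admixture_tracks_genomewide_ancestry():
    from goshawkpop.simulate import (
        SimulationConfig,
        simulate_allele_frequencies,
        simulate_genotypes,
    )
    from goshawkpop.structure import AdmixtureModel

    specs = [("AA", s, min(0.2, 2 * min(s, 1 - s))) for s in
             (0.1, 0.3, 0.5, 0.7, 0.9)]
    cfg = SimulationConfig(
        n_sites=2000,
        region_sizes={"HG": 12, "East": 20},
        drift_F={"HG": 0.4, "East": 0.4},
        source_tiers={"HG": {"tissue": 1.0}, "East": {"tissue": 1.0}},
        admixed_specs=specs,
        seed=11,
    )
    g, meta = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
    genomewide = AdmixtureModel(g, 2).fit(seed=0)
    # panel = 10 strongest-difference sites on distinct scaffolds
    p_hg = g.alt_allele_freq(np.flatnonzero(meta["region"] == "HG"))
    p_e = g.alt_allele_freq(np.flatnonzero(meta["region"] == "East"))
    order = np.argsort(-np.abs(p_hg - p_e))
    chosen, seen = [], set()
    for j in order:
        if g.sites[j].scaffold not in seen:
            chosen.append(int(j))
            seen.add(g.sites[j].scaffold)
        if len(chosen) == 10:
            break
    panel = AimPanel(
        sites=[g.sites[j] for j in chosen],
        site_index=chosen,
        fst_rank=list(range(1, 11)),
        fst=[1.0] * 10,
        p_ref1=p_hg[chosen],
        p_ref2=p_e[chosen],
    )
    panel_fit = admixture_on_panel(g, panel, K=2, seed=0)
    # align cluster order via the island samples
    island = np.flatnonzero(meta["region"] == "HG")
    qg = genomewide.Q[:, np.argmax(genomewide.Q[island].mean(axis=0))]
    qp = panel_fit.Q[:, np.argmax(panel_fit.Q[island].mean(axis=0))]
    from scipy.stats import spearmanr

    rho = spearmanr(qg, qp).statistic
    assert rho > 0.8
    # K = 1 degenerate case
    k1 = admixture_on_panel(g, panel, K=1)
    assert np.allclose(k1.Q, 1.0)
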