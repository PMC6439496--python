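"""Maximum-likelihood ancestry index S and interclass heterozygosity H.

Each locus of an individual carries two allele copies whose source
populations define three ancestry classes with probabilities

    pi11 = S - H/2   (both copies from reference 1)
    pi12 = H         (one copy from each)
    pi22 = 1 - S - H/2  (both copies from reference 2),

feasible on the triangle H <= 2 min(S, 1-S).  Markers need not be
diagnostic: given reference allele frequencies p1, p2 per locus, the
genotype likelihood mixes Hardy-Weinberg terms over the three classes, and
(S, H) is found by an exhaustive feasible-grid search refined by
Nelder-Mead inside the triangle.  F1 hybrids sit at (0.5, 1); pure
reference-1 individuals at (1, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import MISSING, GenotypeMatrix
from .panel import AimPanel
from .simulate import check_feasible

_LOG_FLOOR = 1e-300


@dataclass
class AncestryEstimate:
    sample_id: str
    S: float
    H: float
    logL: float
    n_loci_used: int


def _class_likelihoods(dosage: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Per-locus genotype probability under each ancestry class.

    Returns (A, B, C): likelihood of the observed dosage if both copies
    come from reference 1, one from each, or both from reference 2.
    """
    q1, q2 = 1.0 - p1, 1.0 - p2
    A = np.where(dosage == 2, p1 * p1,
        np.where(dosage == 1, 2.0 * p1 * q1, q1 * q1))
    B = np.where(dosage == 2, p1 * p2,
        np.where(dosage == 1, p1 * q2 + q1 * p2, q1 * q2))
    C = np.where(dosage == 2, p2 * p2,
        np.where(dosage == 1, 2.0 * p2 * q2, q2 * q2))
    return A, B, C


def hi_loglik(
    dosage: np.ndarray, panel: AimPanel, S: float, H: float
) -> float:
    """Log-likelihood of one individual's panel genotypes at (S, H).

    Missing genotypes are skipped; a zero-probability genotype (e.g. a
    genotyping error at a fixed locus) contributes the floor log(1e-300)
    instead of -inf so one bad call cannot destroy the estimate.
    """
    check_feasible(S, H)
    if panel.p_ref1 is None or panel.p_ref2 is None:
        raise ValueError("panel has no reference frequencies attached")
    dosage = np.asarray(dosage)
    use = dosage != MISSING
    A, B, C = _class_likelihoods(
        dosage[use], panel.p_ref1[use], panel.p_ref2[use]
    )
    pi11, pi12, pi22 = S - H / 2.0, H, 1.0 - S - H / 2.0
    lik = pi11 * A + pi12 * B + pi22 * C
    return float(np.log(np.maximum(lik, _LOG_FLOOR)).sum())


def _feasible_grid(step: float) -> np.ndarray:
    s_vals = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    pts = []
    for S in s_vals:
        h_max = 2.0 * min(S, 1.0 - S)
        h_vals = np.round(np.arange(0.0, h_max + step / 2, step), 10)
        h_vals = np.minimum(h_vals, h_max)
        for H in np.unique(h_vals):
            pts.append((S, H))
    return np.asarray(pts)


def estimate_SH(
    dosage: np.ndarray,
    panel: AimPanel,
    sample_id: str = "",
    grid_step: float = 0.005,
    min_loci: int = 7,
    refine: bool = True,
) -> AncestryEstimate | None:
    """Grid search plus local refinement of (S, H) for one individual.

    Returns ``None`` when fewer than ``min_loci`` panel genotypes are
    non-missing (the individual is skipped, mirroring the at-least-7-
    genotypes rule for assay samples).
    """
    dosage = np.asarray(dosage)
    n_used = int((dosage != MISSING).sum())
    if n_used < min_loci:
        return None
    use = dosage != MISSING
    A, B, C = _class_likelihoods(dosage[use], panel.p_ref1[use], panel.p_ref2[use])

    grid = _feasible_grid(grid_step)
    pi11 = grid[:, 0] - grid[:, 1] / 2.0
    pi12 = grid[:, 1]
    pi22 = 1.0 - grid[:, 0] - grid[:, 1] / 2.0
    lik = (
        pi11[:, None] * A[None, :]
        + pi12[:, None] * B[None, :]
        + pi22[:, None] * C[None, :]
    )
    ll = np.log(np.maximum(lik, _LOG_FLOOR)).sum(axis=1)
    best = int(np.argmax(ll))
    S0, H0 = grid[best]
    best_ll = float(ll[best])

    if refine:
        def neg(params):
            S, H = params
            if not (0.0 <= S <= 1.0) or H < 0.0 or H > 2.0 * min(S, 1.0 - S):
                return 1e12
            a = (S - H / 2.0) * A + H * B + (1.0 - S - H / 2.0) * C
            return -float(np.log(np.maximum(a, _LOG_FLOOR)).sum())

        res = optimize.minimize(
            neg, [S0, H0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
        )
        if res.success and -res.fun > best_ll:
            S0, H0 = res.x
            best_ll = -float(res.fun)
            # clip round-off back onto the triangle
            S0 = min(max(S0, 0.0), 1.0)
            H0 = min(max(H0, 0.0), 2.0 * min(S0, 1.0 - S0))
    return AncestryEstimate(sample_id, float(S0), float(H0), best_ll, n_used)


class AncestryResults:
    """Per-sample (S, H) estimates with hybrid-class labels."""

    def __init__(self, estimates: list[AncestryEstimate], skipped: list[str],
                 model: "AncestryModel") -> None:
        self.estimates = estimates
        self.skipped = skipped
        self.model = model

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id, "S": e.S, "H": e.H,
                    "logL": e.logL, "n_loci": e.n_loci_used,
                }
                for e in self.estimates
            ]
        )
        if not df.empty:
            df["class"] = classify_hybrids(df["H"].to_numpy())[0]
            df["cluster1_majority"] = df["S"] > 0.5
        return df

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Ancestry-index / interclass-heterozygosity ML estimates",
            f"  estimated: {len(df)} samples; skipped (<{self.model.min_loci} loci): "
            f"{len(self.skipped)}",
        ]
        if not df.empty:
            lines.append(f"  mean S: {df['S'].mean():.3f}   mean H: {df['H'].mean():.3f}")
            counts = df["class"].value_counts()
            lines.append(
                "  hybrid classes: "
                + ", ".join(f"{k}={int(v)}" for k, v in counts.items())
            )
        return "\n".join(lines)

    def plot_triangle(self, ax=None):
        """(S, H) scatter inside the feasible ancestry triangle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 0.5, 1, 0], [0, 1, 0, 0], color="gray", lw=1)
        df = self.to_frame()
        ax.scatter(df["S"], df["H"], s=14)
        ax.set_xlabel("ancestry index S")
        ax.set_ylabel("interclass heterozygosity H")
        return ax


class AncestryModel:
    """ML (S, H) estimation for every sample of a panel genotype matrix."""

    def __init__(self, g: GenotypeMatrix, panel: AimPanel, min_loci: int = 7) -> None:
        if panel.p_ref1 is None:
            raise ValueError("panel needs reference frequencies (panel_frequencies)")
        self.g = g
        self.panel = panel
        self.min_loci = min_loci
        # map panel sites onto matrix columns by (scaffold, position)
        key = {(s.scaffold, s.position): j for j, s in enumerate(g.sites)}
        self.columns = []
        for s in panel.sites:
            if (s.scaffold, s.position) not in key:
                raise ValueError(f"panel site {s.scaffold}:{s.position} not in matrix")
            self.columns.append(key[(s.scaffold, s.position)])

    def fit(self, grid_step: float = 0.005, refine: bool = True) -> AncestryResults:
        estimates, skipped = [], []
        cols = np.asarray(self.columns)
        for i, sid in enumerate(self.g.sample_ids):
            est = estimate_SH(
                self.g.dosage[i, cols], self.panel, sample_id=sid,
                grid_step=grid_step, min_loci=self.min_loci, refine=refine,
            )
            if est is None:
                skipped.append(sid)
            else:
                estimates.append(est)
        return AncestryResults(estimates, skipped, self)


def classify_hybrids(
    H: np.ndarray, high_H: float = 0.5, mid_H: float = 0.25
) -> tuple[np.ndarray, dict[str, int]]:
    """Label interclass heterozygosity as high / intermediate / low.

    high: H >= 0.5 (early-generation hybrids, boundary inclusive);
    intermediate: 0.25 <= H < 0.5; low: H < 0.25.
    """
    H = np.asarray(H, dtype=float)
    labels = np.where(H >= high_H, "high", np.where(H >= mid_H, "intermediate", "low"))
    counts = {
        "high": int((labels == "high").sum()),
        "intermediate": int((labels == "intermediate").sum()),
        "low": int((labels == "low").sum()),
    }
    return labels, counts


def admixture_on_panel(g: GenotypeMatrix, panel: AimPanel, K: int = 2, seed: int = 0):
    """Admixture fit restricted to the panel loci, for GBS-vs-assay comparison."""
    from .structure import AdmixtureModel

    key = {(s.scaffold, s.position): j for j, s in enumerate(g.sites)}
    cols = [key[(s.scaffold, s.position)] for s in panel.sites]
    return AdmixtureModel(g.take_sites(cols), K).fit(seed=seed)
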