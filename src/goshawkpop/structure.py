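"""Population-structure inference: PCA, ML admixture proportions, DAPC.

The admixture model is the classic binomial mixture: individual i carries
ancestry proportions q_i over K clusters with cluster allele frequencies
p_k, and the log-likelihood over non-missing dosages g_ij is

    L(Q, P) = sum_ij [ g_ij log(sum_k q_ik p_kj)
                       + (2 - g_ij) log(sum_k q_ik (1 - p_kj)) ].

It is maximized by plain EM from a seeded random start, terminating when
the log-likelihood improves by less than ``tol`` (default 1e-9) between
iterations.  Model choice uses genotype-masking cross-validation: random
cells are hidden, the model refit, and hidden dosages scored against their
expectation 2 sum_k q_ik p_kj.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Sample scores and per-axis variance fractions from genotype PCA."""

    scores: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def plot(self, ax=None, labels=None):
        """Scatter of PC1 vs PC2, optionally colored by a label per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if labels is None:
            ax.scatter(self.scores[:, 0], self.scores[:, 1], s=12)
        else:
            for lab in sorted(set(labels)):
                idx = [i for i, l in enumerate(labels) if l == lab]
                ax.scatter(self.scores[idx, 0], self.scores[idx, 1], s=12, label=lab)
            ax.legend(fontsize=7)
        ax.set_xlabel(f"PC1 ({100 * self.variance_explained[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * self.variance_explained[1]:.1f}%)")
        return ax


def _impute_iterative(x: np.ndarray, rank: int, n_rounds: int = 3) -> np.ndarray:
    """Fill nan cells by iterative low-rank SVD reconstruction of site means."""
    missing = np.isnan(x)
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(missing, col_mean[None, :], x)
    if not missing.any():
        return filled
    for _ in range(n_rounds):
        center = filled.mean(axis=0)
        u, s, vt = np.linalg.svd(filled - center, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank] + center
        filled = np.where(missing, np.clip(recon, 0.0, 2.0), x)
    return filled


def run_pca(g: GenotypeMatrix, n_axes: int = 10) -> PcaResult:
    """PCA of the centered dosage matrix with low-rank imputation of missing
    genotypes; axis signs are fixed so each axis's largest-|score| entry is
    positive."""
    if g.n_samples < 2 or g.n_sites < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    x = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))
    rank = min(10, g.n_samples - 1)
    filled = _impute_iterative(x, rank)
    centered = filled - filled.mean(axis=0)
    total_var = (centered ** 2).sum()
    if total_var == 0:
        raise ValueError("zero-variance genotype matrix")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    n_axes = min(n_axes, len(s))
    scores = u[:, :n_axes] * s[:n_axes]
    for a in range(n_axes):
        if scores[np.argmax(np.abs(scores[:, a])), a] < 0:
            scores[:, a] = -scores[:, a]
    var_frac = (s[:n_axes] ** 2) / total_var
    return PcaResult(scores, var_frac, list(g.sample_ids))


# ---------------------------------------------------------------------------
# Admixture model (EM)
# ---------------------------------------------------------------------------

class AdmixtureResults:
    """Fitted ancestry proportions Q, cluster frequencies P, and diagnostics."""

    def __init__(self, model: "AdmixtureModel", Q: np.ndarray, P: np.ndarray,
                 loglik: float, loglik_path: np.ndarray, n_iter: int,
                 converged: bool, seed: int) -> None:
        self.model = model
        self.K = model.K
        self.Q = Q
        self.P = P
        self.loglik = loglik
        self.loglik_path = loglik_path
        self.n_iter = n_iter
        self.converged = converged
        self.seed = seed
        self.cv_error: float | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.model.sample_ids

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q, index=self.sample_ids,
            columns=[f"Q{k + 1}" for k in range(self.K)],
        )

    def summary(self) -> str:
        lines = [
            f"Admixture model fit (K={self.K})",
            f"  samples: {len(self.sample_ids)}   sites: {self.P.shape[1]}",
            f"  log-likelihood: {self.loglik:.6f}",
            f"  EM iterations: {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
        ]
        if self.cv_error is not None:
            lines.append(f"  CV error: {self.cv_error:.6f}")
        mean_q = self.Q.mean(axis=0)
        lines.append("  mean ancestry per cluster: "
                     + ", ".join(f"{v:.3f}" for v in mean_q))
        return "\n".join(lines)

    def plot(self, ax=None, order=None):
        """Stacked-bar ancestry plot, one column per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2))
        q = self.Q if order is None else self.Q[order]
        bottom = np.zeros(len(q))
        for k in range(self.K):
            ax.bar(range(len(q)), q[:, k], bottom=bottom, width=1.0)
            bottom += q[:, k]
        ax.set_ylim(0, 1)
        ax.set_ylabel("ancestry")
        return ax


class AdmixtureModel:
    """Binomial admixture likelihood over a dosage matrix, for a fixed K."""

    def __init__(self, g: GenotypeMatrix, K: int) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > g.n_samples:
            raise ValueError(f"K={K} exceeds the number of samples ({g.n_samples})")
        self.K = K
        self.sample_ids = list(g.sample_ids)
        self._dos = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))

    def loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        f = Q @ P  # expected alt-allele frequency per (i, j)
        g = self._dos
        obs = np.isfinite(g)
        ll = np.where(
            obs,
            np.nan_to_num(g) * np.log(np.maximum(f, _LOG_FLOOR))
            + np.nan_to_num(2.0 - g) * np.log(np.maximum(1.0 - f, _LOG_FLOOR)),
            0.0,
        )
        return float(ll[obs].sum())

    def fit(self, seed: int = 0, tol: float = 1e-9, max_iter: int = 10_000) -> AdmixtureResults:
        """EM to a local maximum from a seeded random start.

        The log-likelihood is non-decreasing across iterations; the run
        stops when the per-iteration gain falls below ``tol``.
        """
        rng = np.random.default_rng(seed)
        g = self._dos
        obs = np.isfinite(g)
        gz = np.nan_to_num(g)          # alt-allele counts, zeros where missing
        hz = np.where(obs, 2.0 - g, 0.0)  # ref-allele counts
        n, m = g.shape
        K = self.K

        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(
            np.nanmean(g, axis=0) / 2.0 + rng.normal(0, 0.05, size=(K, m)), 0.01, 0.99
        )

        path = []
        ll_prev = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            # E-step ratios; responsibilities never materialized per cluster:
            # expected alt copies from cluster k are P_kj * sum_i Q_ik g_ij/FA_ij
            FA = np.maximum(Q @ P, _LOG_FLOOR)          # n x m
            FR = np.maximum(Q @ (1.0 - P), _LOG_FLOOR)
            GA = gz / FA
            GR = hz / FR
            alt_k = P * (Q.T @ GA)                      # K x m
            ref_k = (1.0 - P) * (Q.T @ GR)
            contrib = Q * (GA @ P.T + GR @ (1.0 - P).T)  # n x K
            # M-step
            tot_k = alt_k + ref_k
            P = np.where(tot_k > 0, alt_k / np.maximum(tot_k, _LOG_FLOOR), P)
            Q = contrib / np.maximum(contrib.sum(axis=1, keepdims=True), _LOG_FLOOR)
            ll = self.loglik(Q, P)
            path.append(ll)
            if ll - ll_prev < tol and it > 1:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return AdmixtureResults(
            self, Q, P, ll_prev, np.asarray(path), len(path), converged, seed
        )


def fit_admixture(
    g: GenotypeMatrix, K: int, seed: int = 0, tol: float = 1e-9,
    max_iter: int = 10_000,
) -> AdmixtureResults:
    """Functional wrapper over :class:`AdmixtureModel`."""
    return AdmixtureModel(g, K).fit(seed=seed, tol=tol, max_iter=max_iter)


def admixture_cv(
    g: GenotypeMatrix, K_range, folds: int = 5, replicates: int = 5,
    seed: int = 0, tol: float = 1e-6, max_iter: int = 2_000,
) -> tuple[pd.DataFrame, int]:
    """Genotype-masking cross-validation over K; returns (table, best K).

    Non-missing cells are partitioned into ``folds`` random folds per
    replicate; each fold is hidden in turn, the model refit, and the hidden
    dosages scored by squared error against 2 * sum_k q_ik p_kj.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    obs_idx = np.argwhere(g.dosage != MISSING)
    rows = []
    for K in K_range:
        errors = []
        for rep in range(replicates):
            rng = np.random.default_rng((seed, K, rep))
            perm = rng.permutation(len(obs_idx))
            fold_of = np.arange(len(obs_idx)) % folds
            fold_of = fold_of[np.argsort(perm)]  # random fold assignment
            for fold in range(folds):
                mask_cells = obs_idx[fold_of == fold]
                gm = g.copy()
                gm.dosage[mask_cells[:, 0], mask_cells[:, 1]] = MISSING
                res = AdmixtureModel(gm, K).fit(
                    seed=int(rng.integers(2**31)), tol=tol, max_iter=max_iter
                )
                pred = 2.0 * (res.Q @ res.P)
                truth = g.dosage[mask_cells[:, 0], mask_cells[:, 1]].astype(float)
                errors.append(
                    float(np.mean((truth - pred[mask_cells[:, 0], mask_cells[:, 1]]) ** 2))
                )
        rows.append({"K": K, "cv_error": float(np.mean(errors))})
    table = pd.DataFrame(rows)
    best_K = int(table.loc[table["cv_error"].idxmin(), "K"])
    return table, best_K


# ---------------------------------------------------------------------------
# DAPC-style assignment cross-validation
# ---------------------------------------------------------------------------

def dapc_assignment_cv(
    g: GenotypeMatrix, labels, train_frac: float = 0.6, max_axes: int = 10,
    replicates: int = 20, seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Mean held-out assignment accuracy of LDA on PCA-reduced genotypes.

    For each axis count a = 1..max_axes and replicate, samples are split
    stratified by group (``train_frac`` training), PCA is computed on the
    training genotypes with per-site training-mean imputation, a linear
    discriminant classifier is fit on the first a axes, and accuracy is
    measured on the held-out samples.  Returns the grand mean over the
    (axis, replicate) grid, plus the grid itself.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two labeled groups")
    for grp in groups:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
    x = np.where(g.dosage == MISSING, np.nan, g.dosage.astype(float))

    records = []
    for a in range(1, max_axes + 1):
        for rep in range(replicates):
            rng = np.random.default_rng((seed, a, rep))
            train_idx, test_idx = [], []
            for grp in groups:
                members = np.flatnonzero(labels == grp)
                members = members[rng.permutation(len(members))]
                n_train = max(1, int(round(train_frac * len(members))))
                n_train = min(n_train, len(members) - 1)
                train_idx.extend(members[:n_train])
                test_idx.extend(members[n_train:])
            train_idx = np.asarray(sorted(train_idx))
            test_idx = np.asarray(sorted(test_idx))

            xtr = x[train_idx]
            col_mean = np.nanmean(xtr, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            xtr = np.where(np.isnan(xtr), col_mean[None, :], xtr)
            xte = x[test_idx]
            xte = np.where(np.isnan(xte), col_mean[None, :], xte)

            center = xtr.mean(axis=0)
            u, s, vt = np.linalg.svd(xtr - center, full_matrices=False)
            n_axes = min(a, len(s))
            tr_scores = u[:, :n_axes] * s[:n_axes]
            te_scores = (xte - center) @ vt[:n_axes].T

            clf = LinearDiscriminantAnalysis()
            clf.fit(tr_scores, labels[train_idx])
            acc = float((clf.predict(te_scores) == labels[test_idx]).mean())
            records.append({"axes": a, "replicate": rep, "accuracy": acc})
    grid = pd.DataFrame(records)
    return float(grid["accuracy"].mean()), grid
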