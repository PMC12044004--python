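"""Population structure: PCA and NMF-based ancestry estimation.

Ancestry follows the sNMF idea: factorise the individuals x loci genotype
matrix (alternate-allele dosages rescaled to [0, 1]) as Q F with Q rows on
the probability simplex (per-individual ancestry proportions over K
clusters) and F in [0, 1] (per-cluster allele frequencies).  The number of
clusters is chosen by masking a random subset of genotypes before fitting
and scoring the held-out cross-entropy of their predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "pca",
    "PcaResult",
    "AncestryModel",
    "AncestryResult",
    "snmf_ancestry",
    "choose_K",
    "assign_clusters",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray        # individuals x components
    loadings: np.ndarray      # variables x components
    explained: np.ndarray     # variance fractions, descending


def pca(m: np.ndarray, center: bool = True, scale: bool = False,
        n_components: int | None = None) -> PcaResult:
    """PCA with column-mean imputation of missing entries.

    Explained-variance fractions are over the full rank and sum to 1;
    component signs are fixed so each loading vector's largest-magnitude
    entry is positive (determinism up to that convention).
    """
    X = np.asarray(m, dtype=float).copy()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.take(col_mean, np.nonzero(nan)[1])
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not np.any(X != 0):
        raise ValueError("degenerate input: matrix is constant")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    flip = np.sign(Vt[np.arange(Vt.shape[0]),
                      np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * s
    scores = scores * flip[None, :]
    if n_components is not None:
        scores = scores[:, :n_components]
        Vt = Vt[:n_components]
        explained = explained[:n_components]
    return PcaResult(scores=scores, loadings=Vt.T, explained=explained)


# ---------------------------------------------------------------------------
# Ancestry (simplex-constrained NMF with held-out cross-entropy)
# ---------------------------------------------------------------------------

def _project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of every row onto the probability simplex."""
    n, k = Q.shape
    U = -np.sort(-Q, axis=1)
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(Q - theta[:, None], 0.0)


def _objective(X, W, Q, F):
    R = (X - Q @ F) * W
    return 0.5 * float(np.sum(R * R))


@dataclass
class AncestryResult:
    """Best-run ancestry factorisation.

    Q rows are exact simplex points (sum to one); F entries are allele
    frequencies in [0, 1]; ``cross_entropy`` is the held-out criterion of
    the selected run (lower is better).
    """

    Q: np.ndarray
    F: np.ndarray
    K: int
    cross_entropy: float
    run_cross_entropies: list[float]
    seed: int
    objective_trajectory: list[float] = field(default_factory=list)
    individual_ids: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K)]
        idx = self.individual_ids or [f"ind_{i}" for i in range(self.Q.shape[0])]
        return pd.DataFrame(self.Q, index=idx, columns=cols)

    def to_long(self) -> pd.DataFrame:
        df = self.summary().reset_index(names="individual")
        return df.melt(id_vars="individual", var_name="cluster",
                       value_name="coefficient")


class AncestryModel:
    """sNMF-style ancestry model for a genotype matrix.

    Parameters
    ----------
    g : GenotypeMatrix or ndarray
        Genotype codes 0/1/2 with -1 (or NaN) for missing; callers should
        have MAF-filtered the data beforehand.
    K : int
        Number of ancestral clusters, 1 <= K <= n_individuals.
    """

    def __init__(self, g: GenotypeMatrix | np.ndarray, K: int):
        if isinstance(g, GenotypeMatrix):
            X = g.genotypes.astype(float)
            X[X < 0] = np.nan
            self.individual_ids = list(g.individual_ids)
        else:
            X = np.asarray(g, dtype=float).copy()
            X[X < 0] = np.nan
            self.individual_ids = None
        if not 1 <= K <= X.shape[0]:
            raise ValueError(f"K must be in [1, {X.shape[0]}]")
        self.X = X / 2.0  # dosages in [0, 1]
        self.K = int(K)

    # -- internals ---------------------------------------------------------
    def _fit_single(self, W, rng, max_iter, tol):
        """Alternating projected-gradient descent; monotone by construction."""
        X = np.nan_to_num(self.X)
        n, L = X.shape
        K = self.K
        Q = _project_rows_to_simplex(rng.random((n, K)))
        F = rng.uniform(0.2, 0.8, size=(K, L))
        obj = _objective(X, W, Q, F)
        traj = [obj]
        eta_q, eta_f = 1.0, 1.0
        for _ in range(max_iter):
            # Q block
            G = ((Q @ F - X) * W) @ F.T
            eta_q *= 2.0
            for _bt in range(40):
                Q_new = _project_rows_to_simplex(Q - eta_q * G)
                new = _objective(X, W, Q_new, F)
                if new <= obj:
                    break
                eta_q *= 0.5
            else:
                Q_new, new = Q, obj
            Q, obj = Q_new, new
            # F block
            G = Q.T @ ((Q @ F - X) * W)
            eta_f *= 2.0
            for _bt in range(40):
                F_new = np.clip(F - eta_f * G, 0.0, 1.0)
                new = _objective(X, W, Q, F_new)
                if new <= obj:
                    break
                eta_f *= 0.5
            else:
                F_new, new = F, obj
            F, obj = F_new, new
            traj.append(obj)
            if traj[-2] - traj[-1] < tol * max(traj[-2], _EPS):
                break
        return Q, F, traj

    def _cross_entropy(self, Q, F, mask):
        """Binomial deviance of masked genotypes under predicted dosages."""
        p = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        y = 2.0 * self.X[mask]  # back to 0/1/2 counts
        lp = y * np.log(p[mask]) + (2.0 - y) * np.log(1.0 - p[mask])
        return float(-np.mean(lp) / 2.0)

    def fit(self, n_runs: int = 10, masked_fraction: float = 0.05,
            seed: int = 0, max_iter: int = 200, tol: float = 1e-6
            ) -> AncestryResult:
        """Run ``n_runs`` independent fits and keep the best.

        Per run a random ``masked_fraction`` of the observed genotypes is
        held out of the least-squares fit; the run criterion is the
        cross-entropy of their predictions, so model complexity is scored
        out of sample.  Missing genotypes never enter the residuals.
        """
        observed = ~np.isnan(self.X)
        root = np.random.SeedSequence(seed)
        best = None
        run_ces = []
        for run_seed in root.spawn(n_runs):
            rng = np.random.default_rng(run_seed)
            mask = observed & (rng.random(self.X.shape) < masked_fraction)
            W = (observed & ~mask).astype(float)
            Q, F, traj = self._fit_single(W, rng, max_iter, tol)
            ce = self._cross_entropy(Q, F, mask) if mask.any() else float(
                "nan")
            run_ces.append(ce)
            if best is None or (np.isfinite(ce) and ce < best[0]):
                best = (ce, Q, F, traj)
        ce, Q, F, traj = best
        return AncestryResult(Q=Q, F=F, K=self.K, cross_entropy=ce,
                              run_cross_entropies=run_ces, seed=seed,
                              objective_trajectory=traj,
                              individual_ids=self.individual_ids)


def snmf_ancestry(g, K: int, n_runs: int = 10, masked_fraction: float = 0.05,
                  seed: int = 0, **kw) -> AncestryResult:
    """Convenience wrapper: fit :class:`AncestryModel` and return the best run."""
    return AncestryModel(g, K).fit(n_runs=n_runs,
                                   masked_fraction=masked_fraction,
                                   seed=seed, **kw)


def choose_K(g, K_range=range(2, 15), n_runs: int = 10,
             masked_fraction: float = 0.05, seed: int = 0, **kw):
    """Cross-validation scan over K.

    Returns (table, selected_K): the table holds per-K mean and minimum
    held-out cross-entropy over runs; the selected K minimises the mean
    cross-entropy, ties resolved toward the smaller K.
    """
    K_values = list(K_range)
    rows = []
    results = {}
    for i, K in enumerate(K_values):
        res = snmf_ancestry(g, K, n_runs=n_runs,
                            masked_fraction=masked_fraction,
                            seed=seed + 1000 * i, **kw)
        ces = np.asarray(res.run_cross_entropies, dtype=float)
        rows.append(dict(K=K, mean_cross_entropy=float(np.nanmean(ces)),
                         min_cross_entropy=float(np.nanmin(ces))))
        results[K] = res
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["mean_cross_entropy"].idxmin(), "K"])
    table.attrs["results"] = results
    return table, selected


def assign_clusters(q: AncestryResult, threshold: float = 0.6) -> pd.Series:
    """Assign each individual to its max-coefficient cluster, or "admixed".

    An individual joins cluster argmax(Q row) only when that coefficient is
    at least ``threshold``; otherwise it is labelled admixed.
    """
    idx = q.individual_ids or [f"ind_{i}" for i in range(q.Q.shape[0])]
    best = q.Q.argmax(axis=1)
    out = [
        f"cluster_{b + 1}" if q.Q[i, b] >= threshold else "admixed"
        for i, b in enumerate(best)
    ]
    return pd.Series(out, index=idx, name="cluster")
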