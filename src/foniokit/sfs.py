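"""Folded site-frequency spectra, one- and two-population.

Folding maps allele counts to minor-allele counts, for data where the
ancestral state is unknown.  The joint spectrum of a population pair is
folded by the *total* minor allele: class (i, j) with i + j copies across
both samples is reflected to (nA - i, nB - j) when the total count exceeds
half the pooled sample size (ties keep the variant whose count in the
first population is the smaller).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoldedSFS",
    "JointFoldedSFS",
    "fold_1d",
    "fold_joint",
    "folded_sfs",
    "joint_folded_sfs",
]


def fold_1d(unfolded: np.ndarray) -> np.ndarray:
    """Fold a 1-D spectrum over counts 0..n to minor counts 0..n//2."""
    xi = np.asarray(unfolded, dtype=float)
    n = xi.size - 1
    eta = np.zeros(n // 2 + 1)
    for i in range(n + 1):
        eta[min(i, n - i)] += xi[i]
    return eta


def fold_joint(unfolded: np.ndarray) -> np.ndarray:
    """Fold a joint 2-D spectrum by total minor-allele count."""
    U = np.asarray(unfolded, dtype=float)
    na, nb = U.shape[0] - 1, U.shape[1] - 1
    n = na + nb
    F = np.zeros_like(U)
    for i in range(na + 1):
        for j in range(nb + 1):
            c = i + j
            if 2 * c > n or (2 * c == n and 2 * i > na):
                F[na - i, nb - j] += U[i, j]
            else:
                F[i, j] += U[i, j]
    return F


@dataclass
class FoldedSFS:
    """Minor-allele-count spectrum of one population sample."""

    counts: np.ndarray  # length n//2 + 1
    n_haploid: int
    pop: str = ""

    @property
    def n_sites(self) -> float:
        return float(np.sum(self.counts))

    def proportions(self, exclude_monomorphic: bool = True) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float).copy()
        if exclude_monomorphic:
            c[0] = 0.0
        s = c.sum()
        return c / s if s > 0 else c

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# folded SFS pop={self.pop} n_haploid={self.n_haploid}\n")
            fh.write(" ".join(f"{v:.10g}" for v in self.counts) + "\n")

    @classmethod
    def from_text(cls, path) -> "FoldedSFS":
        with open(path) as fh:
            header = fh.readline().strip()
            counts = np.array([float(x) for x in fh.readline().split()])
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
        return cls(counts=counts, n_haploid=int(meta["n_haploid"]),
                   pop=meta.get("pop", ""))


@dataclass
class JointFoldedSFS:
    """Joint minor-allele spectrum of a population pair.

    ``matrix[i, j]`` counts sites with i minor copies in pop A (haploid
    sample size nA) and j in pop B; only the folded half carries mass.
    """

    matrix: np.ndarray  # (nA + 1, nB + 1)
    pops: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("SFS entries must be non-negative")

    @property
    def sample_sizes(self) -> tuple[int, int]:
        return self.matrix.shape[0] - 1, self.matrix.shape[1] - 1

    @property
    def n_sites(self) -> float:
        return float(self.matrix.sum())

    def proportions(self, exclude_monomorphic: bool = True) -> np.ndarray:
        m = self.matrix.copy()
        if exclude_monomorphic:
            m[0, 0] = 0.0
        s = m.sum()
        return m / s if s > 0 else m

    def to_text(self, path) -> None:
        na, nb = self.sample_sizes
        with open(path, "w") as fh:
            fh.write(
                f"# joint folded SFS popA={self.pops[0]} popB={self.pops[1]} "
                f"nA={na} nB={nb}\n"
            )
            for row in self.matrix:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "JointFoldedSFS":
        with open(path) as fh:
            header = fh.readline().strip()
            rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv)
        return cls(matrix=np.array(rows), pops=(meta.get("popA", "A"),
                                                meta.get("popB", "B")))


# ---------------------------------------------------------------------------
# Observed spectra from genotype matrices
# ---------------------------------------------------------------------------

def _presence_target(n_ind: int, min_presence: float) -> int:
    """Minimum number of genotyped individuals for a site to be used."""
    return int(np.ceil(min_presence * n_ind - 1e-9))


def _downsample_counts(alt, called, n_target, rng):
    """Hypergeometric projection of alt counts to a fixed haploid size."""
    out = np.empty(alt.size, dtype=np.int64)
    for k in range(alt.size):
        if called[k] == n_target:
            out[k] = alt[k]
        else:
            out[k] = rng.hypergeometric(alt[k], called[k] - alt[k], n_target)
    return out


def folded_sfs(g, pop: str, min_presence: float = 0.80, seed: int = 0) -> FoldedSFS:
    """Folded spectrum of one population from called genotypes.

    Sites genotyped in fewer than ``min_presence`` of the population's
    individuals are excluded; sites with more calls than the target are
    down-sampled hypergeometrically (seeded) so every site contributes at
    the same sample size.
    """
    rows = g.pop_index(pop)
    if rows.size == 0:
        raise ValueError(f"population {pop!r} is empty")
    alt, called = g.allele_counts(rows)
    m_min = _presence_target(rows.size, min_presence)
    n_t = 2 * m_min
    if n_t < 2:
        raise ValueError("presence threshold leaves fewer than one individual")
    keep = called >= n_t
    rng = np.random.default_rng(seed)
    alt_p = _downsample_counts(alt[keep], called[keep], n_t, rng)
    unfolded = np.bincount(alt_p, minlength=n_t + 1).astype(float)
    return FoldedSFS(counts=fold_1d(unfolded), n_haploid=n_t, pop=pop)


def joint_folded_sfs(g, pop_a: str, pop_b: str, min_presence: float = 0.80,
                     seed: int = 0) -> JointFoldedSFS:
    """Joint folded spectrum of a population pair.

    The presence filter applies jointly: a site is used only when both
    populations reach their own ``min_presence`` target, then each side is
    projected to its fixed haploid size.
    """
    ra, rb = g.pop_index(pop_a), g.pop_index(pop_b)
    alt_a, called_a = g.allele_counts(ra)
    alt_b, called_b = g.allele_counts(rb)
    na = 2 * _presence_target(ra.size, min_presence)
    nb = 2 * _presence_target(rb.size, min_presence)
    if na < 2 or nb < 2:
        raise ValueError("presence threshold leaves fewer than one individual")
    keep = (called_a >= na) & (called_b >= nb)
    rng = np.random.default_rng(seed)
    pa = _downsample_counts(alt_a[keep], called_a[keep], na, rng)
    pb = _downsample_counts(alt_b[keep], called_b[keep], nb, rng)
    U = np.zeros((na + 1, nb + 1))
    np.add.at(U, (pa, pb), 1.0)
    return JointFoldedSFS(matrix=fold_joint(U), pops=(pop_a, pop_b))
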