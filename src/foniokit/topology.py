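"""Gene-tree topology analyses and drift-covariance population trees.

Three layers of evidence about between-population relationships:

* neighbour-joining trees of individuals in sliding windows,
* topology weighting: for four groups, the fraction of one-tip-per-group
  quartets of each window tree inducing each of the three possible
  unrooted group topologies, and
* a population tree fitted to the genome-wide covariance of allele
  frequencies, where the covariance of two populations' frequency
  deviations equals the drift shared on their root path (migration-free
  Treemix model), with SNP-block bootstrap support.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .diversity import WindowSpec, iter_windows
from .genotypes import GenotypeMatrix

__all__ = [
    "WindowTree",
    "window_nj_trees",
    "twisst_weights",
    "allele_freq_covariance",
    "PopulationTree",
    "fit_population_tree",
    "bootstrap_tree",
]


@dataclass
class WindowTree:
    """Unrooted NJ tree over individual tips for one genomic window."""

    chrom: str
    start: int
    end: int
    newick: str
    n_snps: int

    def tree(self) -> TreeNode:
        import io

        return TreeNode.read(io.StringIO(self.newick),
                             convert_underscores=False)


def _p_distance(sub: np.ndarray) -> np.ndarray:
    """Mean absolute genotype-code difference / 2, pairwise-complete."""
    n = sub.shape[0]
    D = np.zeros((n, n))
    ok = sub >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            if both.sum() == 0:
                D[i, j] = D[j, i] = np.nan
            else:
                d = np.abs(sub[i, both] - sub[j, both]).mean() / 2.0
                D[i, j] = D[j, i] = d
    return D


def window_nj_trees(
    g: GenotypeMatrix,
    w: WindowSpec | None = None,
    min_snps_per_window: int = 20,
) -> list[WindowTree]:
    """Neighbour-joining trees of individuals per sliding window.

    Distances are genotype p-distances over pairwise-complete loci;
    windows with fewer than ``min_snps_per_window`` SNPs, or fewer than 4
    tips with complete distances, are skipped.  Negative NJ branch lengths
    are clipped to zero.
    """
    w = w or WindowSpec()
    out: list[WindowTree] = []
    ids = np.array(g.individual_ids)
    for chrom in dict.fromkeys(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on_chrom]
        for start, end in iter_windows(int(pos.max()), w):
            sel = on_chrom[(pos >= start) & (pos <= end)]
            if sel.size < min_snps_per_window:
                continue
            D = _p_distance(g.genotypes[:, sel])
            usable = ~np.isnan(D).any(axis=1)
            if usable.sum() < 4:
                continue
            dm = DistanceMatrix(D[np.ix_(usable, usable)],
                                ids=list(ids[usable]))
            tree = nj(dm, neg_as_zero=True)
            out.append(WindowTree(chrom=chrom, start=start, end=end,
                                  newick=str(tree).strip(),
                                  n_snps=int(sel.size)))
    return out


# ---------------------------------------------------------------------------
# Topology weighting
# ---------------------------------------------------------------------------

def _topological_tip_distances(tree: TreeNode, tips: list[str]) -> np.ndarray:
    """Node-count path distances between the named tips."""
    for node in tree.traverse():
        node.length = 1.0
    dm = tree.tip_tip_distances(endpoints=tips)
    # reorder to requested tip order
    order = [dm.index(t) for t in tips]
    return dm.data[np.ix_(order, order)]


def twisst_weights(
    trees: list[WindowTree] | list[str],
    group_map: dict[str, list[str]],
    method: str = "auto",
    max_subsamples: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Topology weights of four groups across window trees.

    For each tree, one tip is drawn per group; the pruned quartet supports
    exactly one of the three unrooted pairings of the four groups, decided
    by the four-point condition on topological distances.  Weights are the
    fractions of combinations supporting each pairing — enumerated
    exhaustively when the combination count is at most ``max_subsamples``,
    else sampled uniformly.  Windows where a group has no tips are flagged
    and excluded.

    Returns a per-window DataFrame with columns w_T1..w_T3; genome-wide
    mean weights, the fraction of windows whose maximum-weight topology is
    each pairing, and the topology definitions are in ``df.attrs``.
    """
    groups = list(group_map)
    if len(groups) != 4:
        raise ValueError("topology weighting requires exactly 4 groups")
    g1, g2, g3, g4 = groups
    topologies = [
        f"(({g1},{g2}),({g3},{g4}))",
        f"(({g1},{g3}),({g2},{g4}))",
        f"(({g1},{g4}),({g2},{g3}))",
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for wt in trees:
        tree = wt.tree() if isinstance(wt, WindowTree) else TreeNode.read(
            __import__("io").StringIO(wt), convert_underscores=False)
        tip_names = {t.name for t in tree.tips()}
        members = [[m for m in group_map[gr] if m in tip_names] for gr in groups]
        if any(len(m) == 0 for m in members):
            rows.append((np.nan, np.nan, np.nan, "excluded"))
            continue
        all_tips = [t for mm in members for t in mm]
        D = _topological_tip_distances(tree, all_tips)
        o = {}
        off = 0
        for gi, mm in enumerate(members):
            o[gi] = np.arange(off, off + len(mm))
            off += len(mm)
        n_comb = int(np.prod([len(m) for m in members]))
        if method == "exact" or (method == "auto" and n_comb <= max_subsamples):
            A, B, C, Dd = (o[0], o[1], o[2], o[3])
            s1 = (D[np.ix_(A, B)][:, :, None, None]
                  + D[np.ix_(C, Dd)][None, None, :, :])
            s2 = (D[np.ix_(A, C)][:, None, :, None]
                  + D[np.ix_(B, Dd)][None, :, None, :])
            s3 = (D[np.ix_(A, Dd)][:, None, None, :]
                  + D[np.ix_(B, C)][None, :, :, None])
            mode = "exact"
        else:
            k = max_subsamples
            ia = rng.integers(0, len(members[0]), k)
            ib = rng.integers(0, len(members[1]), k)
            ic = rng.integers(0, len(members[2]), k)
            idd = rng.integers(0, len(members[3]), k)
            a, b, c, d = o[0][ia], o[1][ib], o[2][ic], o[3][idd]
            s1 = D[a, b] + D[c, d]
            s2 = D[a, c] + D[b, d]
            s3 = D[a, d] + D[b, c]
            mode = "sampled"
        S = np.stack([s1, s2, s3], axis=0).reshape(3, -1)
        m = S.min(axis=0)
        is_min = (S == m)
        wsum = is_min / is_min.sum(axis=0, keepdims=True)
        wts = wsum.mean(axis=1)
        rows.append((wts[0], wts[1], wts[2], mode))
    df = pd.DataFrame(rows, columns=["w_T1", "w_T2", "w_T3", "method"])
    valid = df.dropna(subset=["w_T1"])
    wcols = ["w_T1", "w_T2", "w_T3"]
    argmax = valid[wcols].to_numpy().argmax(axis=1) if len(valid) else np.empty(0)
    df.attrs["topologies"] = topologies
    df.attrs["mean_weights"] = valid[wcols].mean().to_dict() if len(valid) else {}
    df.attrs["max_weight_fraction"] = {
        topologies[t]: float(np.mean(argmax == t)) for t in range(3)
    }
    df.attrs["n_windows_used"] = int(len(valid))
    return df


# ---------------------------------------------------------------------------
# Allele-frequency covariance and drift trees
# ---------------------------------------------------------------------------

def allele_freq_covariance(g: GenotypeMatrix, pops: list[str],
                           scale: bool = True) -> pd.DataFrame:
    """Bias-corrected covariance of population allele frequencies.

    Per SNP, sample frequencies are centred by the unweighted
    across-population mean and (by default) scaled by sqrt(pbar(1-pbar));
    the covariance is averaged across SNPs and the within-population
    sampling variance p(1-p)/(2n) (mean over SNPs) is subtracted from the
    diagonal.  SNPs uncalled in any population, or monomorphic across all,
    are dropped.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if g.n_loci < 2:
        raise ValueError("need at least two SNPs")
    freqs, ns = [], []
    for p in pops:
        alt, called = g.allele_counts(g.pop_index(p))
        if called.max() == 0:
            raise ValueError(f"population {p!r} has no called genotypes")
        freqs.append(np.where(called > 0, alt / np.maximum(called, 1), np.nan))
        ns.append(called.astype(float))
    P = np.vstack(freqs)          # pops x snps
    N = np.vstack(ns)             # called haploids
    ok = ~np.isnan(P).any(axis=0)
    pbar = P[:, ok].mean(axis=0)
    het = pbar * (1.0 - pbar)
    poly = het > 0
    P = P[:, ok][:, poly]
    N = N[:, ok][:, poly]
    pbar, het = pbar[poly], het[poly]
    if P.shape[1] < 2:
        raise ValueError("fewer than two usable SNPs")
    X = P - pbar[None, :]
    if scale:
        X = X / np.sqrt(het)[None, :]
    W = (X @ X.T) / X.shape[1]
    correction = P * (1.0 - P) / N
    if scale:
        correction = correction / het[None, :]
    W[np.diag_indices_from(W)] -= correction.mean(axis=1)
    return pd.DataFrame(W, index=pops, columns=pops)


def _rooted_topologies(taxa: list[str]):
    """All rooted binary tree shapes over the taxa, as nested tuples."""

    def insert_everywhere(tree, x):
        yield (tree, x)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insert_everywhere(left, x):
                yield (t, right)
            for t in insert_everywhere(right, x):
                yield (left, t)

    trees = [taxa[0]]
    for x in taxa[1:]:
        trees = [t for tr in trees for t in insert_everywhere(tr, x)]
    return trees


def _clades(tree) -> list[frozenset]:
    """Descendant-leaf sets of every non-root node (one per branch)."""
    out: list[frozenset] = []

    def leafset(t) -> frozenset:
        if not isinstance(t, tuple):
            return frozenset([t])
        ls = leafset(t[0]) | leafset(t[1])
        return ls

    def walk(t, is_root):
        if not is_root:
            out.append(leafset(t))
        if isinstance(t, tuple):
            walk(t[0], False)
            walk(t[1], False)

    walk(tree, True)
    return out


@dataclass
class PopulationTree:
    """Drift tree fitted to an allele-frequency covariance matrix."""

    newick: str
    pops: list[str]
    branch_lengths: dict
    W: np.ndarray
    W_hat: np.ndarray
    residuals: np.ndarray
    variance_explained: float

    def summary(self) -> str:
        lines = [f"population tree: {self.newick}",
                 f"variance explained: {self.variance_explained:.6f}",
                 "branch drift lengths:"]
        for clade, ell in sorted(self.branch_lengths.items(),
                                 key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            lines.append(f"  {{{','.join(sorted(clade))}}}: {ell:.6g}")
        return "\n".join(lines)


def _project_psd(W: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((W + W.T) / 2.0)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


def fit_population_tree(W, pops: list[str] | None = None,
                        root_label: str | None = None) -> PopulationTree:
    """Least-squares drift tree for a covariance matrix of <= 6 populations.

    The drift model predicts cov(i, j) as the summed branch length shared
    on the root-to-MRCA(i, j) path; because the observed matrix is built
    from frequencies centred across populations, the prediction is centred
    the same way before comparison.  All rooted topologies are scanned
    (exhaustive up to 6 taxa), branch lengths are fitted by non-negative
    least squares, and the best tree minimises the residual sum of squares
    (ties broken by newick string order).
    """
    if isinstance(W, pd.DataFrame):
        pops = list(W.columns)
        W = W.to_numpy()
    if pops is None:
        raise ValueError("pops required when W is a bare array")
    P = len(pops)
    if P > 6:
        raise ValueError("exhaustive topology search supports at most 6 populations")
    W = np.asarray(W, dtype=float)
    vals = np.linalg.eigvalsh((W + W.T) / 2.0)
    if vals.min() < -1e-8 * max(1.0, abs(vals).max()):
        warnings.warn("covariance not PSD after correction; projecting")
        W = _project_psd(W)
    A = np.eye(P) - np.ones((P, P)) / P
    idx = {p: i for i, p in enumerate(pops)}
    sst = float(np.sum((W - W.mean()) ** 2))
    tol = 1e-9 * max(sst, 1e-30)
    best = None
    for shape in _rooted_topologies(pops):
        clades = _clades(shape)
        if root_label is not None:
            if not isinstance(shape, tuple):
                continue
            top = (_leafset(shape[0]), _leafset(shape[1]))
            if frozenset([root_label]) not in top:
                continue
        cols = []
        for cl in clades:
            M = np.zeros((P, P))
            members = [idx[p] for p in cl]
            M[np.ix_(members, members)] = 1.0
            cols.append((A @ M @ A).ravel())
        design = np.column_stack(cols)
        ell, _ = nnls(design, W.ravel())
        What = (design @ ell).reshape(P, P)
        ssr = float(np.sum((W - What) ** 2))
        # scale-invariant tie-break: near-equal fits resolved by the
        # topology's string representation
        shape_str = repr(shape)
        if (best is None or ssr < best[0] - tol
                or (ssr < best[0] + tol and shape_str < best[1])):
            best = (ssr, shape_str, shape, clades, ell, What)
    ssr, _, shape, clades, ell, What = best
    nwk = _render_newick(shape, clades, ell)
    ve = 1.0 - ssr / sst if sst > 0 else 1.0
    return PopulationTree(
        newick=nwk,
        pops=pops,
        branch_lengths={cl: float(l) for cl, l in zip(clades, ell)},
        W=W,
        W_hat=What,
        residuals=W - What,
        variance_explained=ve,
    )


def _leafset(t) -> frozenset:
    if not isinstance(t, tuple):
        return frozenset([t])
    return _leafset(t[0]) | _leafset(t[1])


def _render_newick(shape, clades, lengths) -> str:
    ln = {cl: l for cl, l in zip(clades, lengths)}

    def rec(t, is_root):
        body = (str(t) if not isinstance(t, tuple)
                else f"({rec(t[0], False)},{rec(t[1], False)})")
        if is_root:
            return body
        return f"{body}:{ln[_leafset(t)]:.6g}"

    return rec(shape, True) + ";"


def bootstrap_tree(g: GenotypeMatrix, pops: list[str], block_size: int = 500,
                   n_boot: int = 100, seed: int = 0, root_label=None,
                   scale: bool = True):
    """Block-bootstrap support for the drift tree.

    SNPs are grouped into contiguous blocks of ``block_size`` (linkage-
    aware resampling unit); blocks are resampled with replacement, the
    covariance tree is refitted per replicate, and each bipartition's
    support is the fraction of replicates containing it.  Returns
    (majority-rule consensus newick, support dict keyed by leaf set).
    """
    n_blocks = g.n_loci // block_size
    if n_blocks < 2:
        raise ValueError("not enough SNPs for two bootstrap blocks")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    trees = []
    everyone = frozenset(pops)
    ref = sorted(pops)[0]
    for _ in range(n_boot):
        blocks = rng.integers(0, n_blocks, size=n_blocks)
        sel = np.concatenate([
            np.arange(b * block_size, (b + 1) * block_size) for b in blocks
        ])
        sel.sort()
        sub = g.take_loci(np.unique(sel))
        Wb = allele_freq_covariance(sub, pops, scale=scale)
        fit = fit_population_tree(Wb, root_label=root_label)
        trees.append(fit)
        # canonical unrooted bipartitions: the side not holding the
        # reference taxon; trivial splits are skipped
        seen = set()
        for cl in fit.branch_lengths:
            side = everyone - cl if ref in cl else cl
            if 2 <= len(side) <= len(pops) - 2:
                seen.add(side)
        for side in seen:
            counts[side] = counts.get(side, 0) + 1
    support = {cl: c / n_boot for cl, c in counts.items()}
    majority = sorted(
        (cl for cl, s in support.items() if s > 0.5),
        key=lambda cl: -len(cl),
    )
    # greedily keep mutually compatible clades (nested or disjoint)
    kept: list[frozenset] = []
    for cl in majority:
        if all(cl <= k or k <= cl or not (cl & k) for k in kept):
            kept.append(cl)
    consensus = _splits_to_newick(set(pops), kept, support) + ";"
    return consensus, support


def _splits_to_newick(all_taxa: set, clades: list[frozenset],
                      support: dict) -> str:
    children = [cl for cl in clades if cl < all_taxa]
    direct = [cl for cl in children
              if not any(cl < other for other in children)]
    covered = set().union(*direct) if direct else set()
    parts = []
    for cl in sorted(direct, key=lambda c: sorted(c)[0]):
        inner = _splits_to_newick(set(cl),
                                  [c for c in clades if c < cl], support)
        parts.append(f"{inner}{support.get(frozenset(cl), 1.0):.2f}"
                     if len(cl) > 1 else inner)
    for taxon in sorted(all_taxa - covered):
        parts.append(str(taxon))
    body = "(" + ",".join(parts) + ")" if len(parts) > 1 else parts[0]
    return body
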