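"""Sliding-window diversity and divergence statistics.

Per window and population: segregating sites S, nucleotide diversity pi,
Watterson's theta and Tajima's D; between populations: dxy and the net
divergence da = dxy - (pi_A + pi_B)/2; plus linkage-disequilibrium decay
(r^2 against distance).  Missing genotypes are handled with
pairwise-complete allele counts per site; per-site values are normalised
by the full window length in bp (the number of SNPs actually used is
reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "WindowSpec",
    "window_diversity",
    "dxy_da",
    "ld_decay",
    "tajimas_d_constants",
]


@dataclass
class WindowSpec:
    """Sliding windows: ``size`` bp wide every ``step`` bp, 1-based closed."""

    size: int = 50_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.size:
            raise ValueError("step must not exceed window size")


def iter_windows(max_pos: int, w: WindowSpec):
    """Yield (start, end) pairs tiling 1..max_pos."""
    start = 1
    while start <= max_pos:
        yield start, start + w.size - 1
        start += w.step


def tajimas_d_constants(n: int) -> dict[str, float]:
    """Standard constants for Tajima's D at haploid sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def _pairwise_site_stats(alt: np.ndarray, called: np.ndarray):
    """Per-site mean pairwise difference c(n-c)/C(n,2), requiring n >= 2."""
    ok = called >= 2
    n = called[ok].astype(float)
    c = alt[ok].astype(float)
    pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return pi, ok


def window_diversity(
    g: GenotypeMatrix,
    pops: list[str] | None = None,
    w: WindowSpec | None = None,
    max_locus_missing_within_pop: float = 0.20,
) -> pd.DataFrame:
    """Sliding-window S, pi, theta_W and Tajima's D per population.

    Loci missing in more than ``max_locus_missing_within_pop`` of a
    population's individuals are dropped for that population.  theta_W uses
    S / a_{n-1} with n the median haploid sample size among used loci;
    Tajima's D uses the standard variance estimator and is NaN when S = 0.
    Per-site values divide by the window length in bp.
    """
    w = w or WindowSpec()
    if pops is None:
        if g.pop_labels is None:
            raise ValueError("no population labels available")
        pops = list(dict.fromkeys(g.pop_labels))
    rows_by_pop = {p: g.pop_index(p) for p in pops}
    out = []
    for chrom in dict.fromkeys(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on_chrom]
        for start, end in iter_windows(int(pos.max()), w):
            sel = on_chrom[(pos >= start) & (pos <= end)]
            for p in pops:
                rows = rows_by_pop[p]
                sub = g.genotypes[np.ix_(rows, sel)]
                miss = (sub == -1).mean(axis=0) if sel.size else np.empty(0)
                use = miss <= max_locus_missing_within_pop
                sub = sub[:, use]
                called = 2 * (sub >= 0).sum(axis=0)
                alt = np.where(sub >= 0, sub, 0).sum(axis=0)
                pi_site, ok = _pairwise_site_stats(alt, called)
                seg = (alt[ok] > 0) & (alt[ok] < called[ok])
                S = int(seg.sum())
                pi_sum = float(pi_site.sum())
                n_med = int(np.median(called[ok])) if ok.any() else 0
                theta_sum, D = np.nan, np.nan
                if n_med >= 2:
                    k = tajimas_d_constants(n_med)
                    theta_sum = S / k["a1"]
                    if S > 0:
                        var = k["e1"] * S + k["e2"] * S * (S - 1)
                        if var > 0:
                            D = (pi_sum - theta_sum) / np.sqrt(var)
                out.append(
                    dict(chrom=chrom, start=start, end=end, pop=p, S=S,
                         pi=pi_sum / w.size,
                         theta_w=(theta_sum / w.size) if np.isfinite(theta_sum) else np.nan,
                         tajima_d=D, n_used=n_med, sites_used=int(use.sum())))
    return pd.DataFrame(out)


def dxy_da(g: GenotypeMatrix, pop_a: str, pop_b: str,
           w: WindowSpec | None = None) -> pd.DataFrame:
    """Per-window between-population divergence dxy and net divergence da.

    dxy averages per-site differences over all cross-population sequence
    pairs (pairwise-complete allele counts); da subtracts the mean of the
    within-population diversities computed on the same windows, so
    da = dxy - (pi_a + pi_b)/2 holds identically in the output.
    """
    w = w or WindowSpec()
    ra, rb = g.pop_index(pop_a), g.pop_index(pop_b)
    if ra.size == 0 or rb.size == 0:
        raise ValueError("both populations need at least one individual")
    out = []
    for chrom in dict.fromkeys(g.chrom):
        on_chrom = np.flatnonzero(g.chrom == chrom)
        pos = g.pos[on_chrom]
        for start, end in iter_windows(int(pos.max()), w):
            sel = on_chrom[(pos >= start) & (pos <= end)]
            ga = g.genotypes[np.ix_(ra, sel)]
            gb = g.genotypes[np.ix_(rb, sel)]
            ca = np.where(ga >= 0, ga, 0).sum(axis=0)
            na = 2 * (ga >= 0).sum(axis=0)
            cb = np.where(gb >= 0, gb, 0).sum(axis=0)
            nb = 2 * (gb >= 0).sum(axis=0)
            both = (na >= 1) & (nb >= 1)
            dxy_sum = float(np.sum(
                (ca[both] * (nb[both] - cb[both]) + (na[both] - ca[both]) * cb[both])
                / (na[both] * nb[both])
            ))
            pi_a = float(_pairwise_site_stats(ca, na)[0].sum())
            pi_b = float(_pairwise_site_stats(cb, nb)[0].sum())
            dxy = dxy_sum / w.size
            pa, pb = pi_a / w.size, pi_b / w.size
            out.append(dict(chrom=chrom, start=start, end=end,
                            dxy=dxy, pi_a=pa, pi_b=pb,
                            da=dxy - (pa + pb) / 2.0,
                            sites_used=int(both.sum())))
    return pd.DataFrame(out)


def ld_decay(g: GenotypeMatrix, pop: str, max_dist: int = 500_000,
             bin_width: int = 1_000) -> pd.DataFrame:
    """Binned mean r^2 between genotype codes against physical distance.

    Pairs are intra-chromosomal with distance <= ``max_dist``; r is the
    Pearson correlation over pairwise-complete individuals; monomorphic
    pairs (undefined r) are skipped and counted.
    """
    rows = g.pop_index(pop)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_skipped = 0
    for chrom in dict.fromkeys(g.chrom):
        sel = np.flatnonzero(g.chrom == chrom)
        if sel.size < 2:
            continue
        sub = g.genotypes[np.ix_(rows, sel)].astype(float)
        sub[sub < 0] = np.nan
        corr = pd.DataFrame(sub).corr(min_periods=2).to_numpy()
        pos = g.pos[sel]
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(sel.size, k=1)
        d = dist[iu]
        r = corr[iu]
        in_range = d <= max_dist
        r2 = r[in_range] ** 2
        d = d[in_range]
        nan = ~np.isfinite(r2)
        n_skipped += int(nan.sum())
        for dd, rr in zip(d[~nan], r2[~nan]):
            b = int(dd // bin_width)
            sums[b] = sums.get(b, 0.0) + float(rr)
            counts[b] = counts.get(b, 0) + 1
    rows_out = [
        dict(dist_bp=(b + 0.5) * bin_width, mean_r2=sums[b] / counts[b],
             n_pairs=counts[b])
        for b in sorted(sums)
    ]
    df = pd.DataFrame(rows_out, columns=["dist_bp", "mean_r2", "n_pairs"])
    df.attrs["n_monomorphic_pairs_skipped"] = n_skipped
    return df
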