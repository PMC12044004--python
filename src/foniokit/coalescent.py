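"""Coalescent simulation of genotypes, window genealogies and sequences.

The generator emulates the study system this package targets: four
*Digitaria* populations arranged as two cultivated/wild pairs, a deep
between-pair divergence, a post-divergence bottleneck in each cultivated
lineage followed by a recent expansion, infinite-sites mutation, and
optional genotype missingness.  Loci (and windows) are non-recombining
internally and unlinked from each other.

Two simulation paths share the same demographic-event representation:

* a Python genealogy simulator that returns full node tables (used for
  window trees, sequences and genotype matrices), and
* the compiled kernel in :mod:`foniokit._kernel` that accumulates joint
  site-frequency-spectrum branch weights (used by the demographic
  inference machinery, where millions of genealogies are needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demographics import DemographicModel, ModelError
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimulatedDataset",
    "simulate_genealogy",
    "simulate_unlinked_snps",
    "simulate_windows",
    "emit_sequences",
    "inject_missingness",
]


@dataclass
class Window:
    chrom: str
    start: int  # 1-based, closed
    end: int


@dataclass
class SimulatedDataset:
    """Simulation output: genotypes plus optional genealogies/haplotypes."""

    genotypes: GenotypeMatrix
    seed: int
    windows: list[Window] = field(default_factory=list)
    true_trees: list[str] = field(default_factory=list)  # newick per window/locus
    # per window/locus: (positions within unit, haplotype matrix 2n x S)
    haplotypes: list[tuple[np.ndarray, np.ndarray]] | None = None
    unit_length: int = 0


def _sample_slots(model: DemographicModel, samples: dict[str, int]) -> np.ndarray:
    """Haploid sample counts aligned to the model's population slots."""
    unknown = set(samples) - set(model.pop_sizes)
    if unknown:
        raise ModelError(f"samples reference unknown populations: {sorted(unknown)}")
    out = np.zeros(len(model.pop_sizes), dtype=np.int64)
    for i, p in enumerate(model.pop_sizes):
        out[i] = 2 * int(samples.get(p, 0))
    if out.sum() < 2:
        raise ModelError("need at least two haploid samples in total")
    return out


def simulate_genealogy(model: DemographicModel, haploid_samples: dict[str, int],
                       rng: np.random.Generator):
    """Simulate one genealogy; return (parent, time, leaf_pops).

    ``parent``/``time`` are arrays over the 2n-1 nodes (root parent = -1);
    leaves are nodes 0..n-1 ordered by population blocks in model slot
    order.  ``leaf_pops`` gives the population name per leaf.
    """
    idx, sizes0, ev_time, ev_kind, ev_a, ev_b = model.compile_events()
    pops = list(model.pop_sizes)
    counts = np.zeros(len(pops), dtype=np.int64)
    for p, k in haploid_samples.items():
        counts[idx[p]] = k
    n = int(counts.sum())
    if n < 2:
        raise ModelError("need at least two haploid samples")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1, dtype=np.float64)
    leaf_pops: list[str] = []
    active: list[int] = []
    active_pop: list[int] = []
    nid = 0
    for s, p in enumerate(pops):
        for _ in range(counts[s]):
            active.append(nid)
            active_pop.append(s)
            leaf_pops.append(p)
            nid += 1
    sizes = sizes0.copy()
    t = 0.0
    iev = 0
    n_ev = len(ev_time)
    from .demographics import EV_JOIN

    while len(active) > 1:
        kpop = np.bincount(active_pop, minlength=len(pops))
        rates = np.where(kpop > 1, kpop * (kpop - 1) / 2.0 / (2.0 * sizes), 0.0)
        total = rates.sum()
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        if iev < n_ev and t + dt > ev_time[iev]:
            t = ev_time[iev]
            if ev_kind[iev] == EV_JOIN:
                a, b = ev_a[iev], int(ev_b[iev])
                active_pop = [b if q == a else q for q in active_pop]
            else:
                sizes[ev_a[iev]] = ev_b[iev]
            iev += 1
            continue
        if not np.isfinite(dt):
            raise ModelError("remaining lineages can never coalesce; check splits")
        t += dt
        cpop = int(rng.choice(len(pops), p=rates / total))
        members = [i for i, q in enumerate(active_pop) if q == cpop]
        i1, i2 = rng.choice(len(members), size=2, replace=False)
        a_idx, b_idx = members[i1], members[i2]
        na, nb = active[a_idx], active[b_idx]
        parent[na] = nid
        parent[nb] = nid
        times[nid] = t
        for j in sorted((a_idx, b_idx), reverse=True):
            del active[j]
            del active_pop[j]
        active.append(nid)
        active_pop.append(cpop)
        nid += 1
    return parent, times, leaf_pops


def _children_lists(parent: np.ndarray) -> list[list[int]]:
    ch: list[list[int]] = [[] for _ in range(parent.size)]
    for v, p in enumerate(parent):
        if p >= 0:
            ch[p].append(v)
    return ch


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    """Descendant-leaf index arrays per node (nodes are time-ordered)."""
    sets: list[list[int]] = [[] for _ in range(parent.size)]
    for v in range(n_leaves):
        sets[v] = [v]
    # internal nodes were created in coalescence (time) order, so children
    # always precede parents in index order
    for v in range(parent.size - 1):
        sets[parent[v]].extend(sets[v])
    return [np.array(s, dtype=np.int64) for s in sets]


def newick_from_table(parent: np.ndarray, times: np.ndarray,
                      labels: list[str]) -> str:
    """Unrooted-style newick (rooted at the MRCA) with branch lengths."""
    ch = _children_lists(parent)
    root = int(np.flatnonzero(parent == -1)[0])

    def rec(v: int) -> str:
        if not ch[v]:
            return labels[v]
        inner = ",".join(rec(c) for c in ch[v])
        return f"({inner})"

    def rec_len(v: int) -> str:
        bl = times[parent[v]] - times[v] if parent[v] >= 0 else 0.0
        if not ch[v]:
            return f"{labels[v]}:{bl:.6g}"
        inner = ",".join(rec_len(c) for c in ch[v])
        if parent[v] >= 0:
            return f"({inner}):{bl:.6g}"
        return f"({inner})"

    return rec_len(root) + ";"


def _drop_mutations(parent, times, n_leaves, mu, length, rng):
    """Infinite-sites mutations: (positions, hap matrix n_leaves x S).

    Sites get distinct integer positions in 1..length; the number of
    segregating sites is Poisson(mu * length * total branch length), capped
    at ``length`` distinct coordinates.
    """
    edges = np.flatnonzero(parent >= 0)
    blens = times[parent[edges]] - times[edges]
    total = float(blens.sum())
    n_mut = rng.poisson(mu * length * total)
    n_mut = min(int(n_mut), int(length))
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.zeros((n_leaves, 0), dtype=np.int8)
    onto = rng.choice(edges.size, size=n_mut, p=blens / total)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_mut, replace=False))
    leaf_sets = _leaf_sets(parent, n_leaves)
    H = np.zeros((n_leaves, n_mut), dtype=np.int8)
    for s, e in enumerate(onto):
        H[leaf_sets[edges[e]], s] = 1
    return pos, H


def _dataset_from_units(model, samples, units, unit_len, seed, chrom_per_unit,
                        keep_trees):
    """Assemble a SimulatedDataset from independently simulated units."""
    rng = np.random.default_rng(seed)
    hap = {p: 2 * int(k) for p, k in samples.items() if k > 0}
    ind_ids: list[str] = []
    ind_pops: list[str] = []
    for p in model.pop_sizes:
        for i in range(samples.get(p, 0)):
            ind_ids.append(f"{p}_{i}")
            ind_pops.append(p)
    n_ind = len(ind_ids)
    all_chrom, all_pos, geno_cols = [], [], []
    trees, haplos, windows = [], [], []
    for u in range(units):
        parent, times, leaf_pops = simulate_genealogy(model, hap, rng)
        n_leaves = len(leaf_pops)
        pos, H = _drop_mutations(parent, times, n_leaves, model.mu, unit_len, rng)
        chrom, offset = chrom_per_unit(u)
        windows.append(Window(chrom, offset + 1, offset + unit_len))
        if keep_trees:
            labels = [f"{ind_ids[i // 2]}|{i % 2}" for i in range(n_leaves)]
            trees.append(newick_from_table(parent, times, labels))
        haplos.append((pos, H))
        if pos.size:
            G = H[0::2] + H[1::2]  # consecutive haplotypes -> one diploid
            all_chrom.extend([chrom] * pos.size)
            all_pos.extend((offset + pos).tolist())
            geno_cols.append(G)
    if geno_cols:
        G = np.concatenate(geno_cols, axis=1).astype(np.int8)
    else:
        G = np.zeros((n_ind, 0), dtype=np.int8)
    gm = GenotypeMatrix(
        genotypes=G,
        chrom=np.array(all_chrom, dtype=object),
        pos=np.array(all_pos, dtype=np.int64),
        individual_ids=ind_ids,
        pop_labels=ind_pops,
    )
    return SimulatedDataset(
        genotypes=gm,
        seed=seed,
        windows=windows,
        true_trees=trees,
        haplotypes=haplos,
        unit_length=unit_len,
    )


def simulate_unlinked_snps(model: DemographicModel, samples: dict[str, int],
                           n_loci: int, locus_len: int = 1000,
                           seed: int = 0) -> SimulatedDataset:
    """Simulate ``n_loci`` independent non-recombining loci.

    Each locus lives on its own contig (free recombination between loci);
    within a locus all SNPs share one genealogy.  ``samples`` gives diploid
    counts per population; genotypes pair consecutive haplotypes.
    """
    if locus_len < 1:
        raise ValueError("locus_len must be >= 1")
    return _dataset_from_units(
        model, samples, n_loci, int(locus_len), seed,
        chrom_per_unit=lambda u: (f"locus_{u}", 0),
        keep_trees=False,
    )


def simulate_windows(model: DemographicModel, samples: dict[str, int],
                     n_windows: int, window_len: int = 50_000,
                     seed: int = 0) -> SimulatedDataset:
    """Simulate contiguous windows on one chromosome, one genealogy each.

    Window ``u`` covers positions [u*window_len + 1, (u+1)*window_len] of
    chromosome "1"; the true genealogy per window is recorded as newick so
    sliding-window statistics and topology weighting can be validated
    against the generating trees.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    return _dataset_from_units(
        model, samples, n_windows, int(window_len), seed,
        chrom_per_unit=lambda u: ("1", u * int(window_len)),
        keep_trees=True,
    )


_BASES = np.array(list("ACGT"))


def emit_sequences(dataset: SimulatedDataset, out_dir, ref_base_policy="random"):
    """Write per-individual FASTA files from simulated haplotypes.

    Each simulated unit gets a fixed random background sequence (derived
    from the dataset seed, so reproducible); at each segregating position
    carriers of the derived allele receive a different base.  Every
    individual's two haplotype sequences are written per unit.  Returns the
    list of FASTA paths, one per individual.
    """
    import os

    if dataset.haplotypes is None:
        raise ValueError("dataset carries no haplotypes")
    rng = np.random.default_rng(np.random.SeedSequence([dataset.seed, 917]))
    ids = dataset.genotypes.individual_ids
    n_ind = len(ids)
    os.makedirs(out_dir, exist_ok=True)
    L = dataset.unit_length
    per_ind: list[list[str]] = [[] for _ in range(n_ind)]
    for u, (pos, H) in enumerate(dataset.haplotypes):
        if ref_base_policy == "random":
            background = rng.integers(0, 4, size=L)
        else:
            background = np.zeros(L, dtype=np.int64)  # all 'A'
        alt = (background[pos - 1] + 1 + rng.integers(0, 3, size=pos.size)) % 4
        for i in range(n_ind):
            for h in (0, 1):
                seq = background.copy()
                carried = H[2 * i + h].astype(bool)
                seq[pos[carried] - 1] = alt[carried]
                per_ind[i].append(
                    f">{ids[i]}|unit{u}|hap{h}\n" + "".join(_BASES[seq]) + "\n"
                )
    paths = []
    for i, recs in enumerate(per_ind):
        p = os.path.join(out_dir, f"{ids[i]}.fasta")
        with open(p, "w") as fh:
            fh.writelines(recs)
        paths.append(p)
    return paths


def inject_missingness(g: GenotypeMatrix, rate=None, per_indiv_rates=None,
                       seed: int = 0) -> GenotypeMatrix:
    """Set genotype cells missing independently at the given rate(s).

    ``rate`` applies globally; ``per_indiv_rates`` (mapping id -> rate)
    overrides per individual, emulating the strong between-species
    differences in missingness seen when several species are mapped to a
    single reference genome.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    rates = np.zeros(g.n_individuals)
    if rate is not None:
        rates[:] = rate
    if per_indiv_rates is not None:
        for i, ind in enumerate(g.individual_ids):
            if ind in per_indiv_rates:
                rates[i] = per_indiv_rates[ind]
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("missingness rates must be in [0, 1]")
    mask = rng.random(g.genotypes.shape) < rates[:, None]
    gt = g.genotypes.copy()
    gt[mask] = MISSING
    return dataclasses.replace(g, genotypes=gt)
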