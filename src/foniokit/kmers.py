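"""Reference-free k-mer diversity: canonical k-mer tables and Jaccard.

Sequences are decomposed into canonical 31-mers (the lexicographic minimum
of a k-mer and its reverse complement, so counting is strand-agnostic), a
presence/absence table across individuals is filtered on minor allele
count/frequency, down-sampled to a fixed table size, and within-group
Jaccard dissimilarities are computed over repeated random sub-tables —
a mapping-free analogue of nucleotide diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "canonical_kmers",
    "KmerTable",
    "build_kmer_table",
    "sample_kmer_table",
    "jaccard_dissimilarity",
    "kmer_matrix_for_pca",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int = 31) -> set[str]:
    """Canonical k-mers of a sequence; windows containing N are skipped."""
    if k % 2 == 0:
        raise ValueError("k must be odd so no k-mer is its own reverse complement")
    seq = seq.upper()
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


@dataclass
class KmerTable:
    """Canonical k-mer x individual presence/absence matrix."""

    k: int
    kmers: list[str]
    presence: np.ndarray  # bool, (n_kmers, n_individuals)
    individual_ids: list[str]
    filter_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.kmers), len(self.individual_ids)):
            raise ValueError("presence shape mismatch")
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("duplicate k-mers in table")

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.presence.astype(int), index=self.kmers,
                          columns=self.individual_ids)
        df.to_csv(path, sep="\t", index_label="kmer")

    @classmethod
    def from_tsv(cls, path) -> "KmerTable":
        df = pd.read_csv(path, sep="\t", index_col="kmer")
        return cls(k=len(df.index[0]), kmers=list(df.index),
                   presence=df.to_numpy(dtype=bool),
                   individual_ids=list(df.columns))


def _iter_fasta(path):
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield str(rec.seq)


def build_kmer_table(
    fasta_by_individual: dict[str, str],
    k: int = 31,
    mac_min: int = 2,
    maf_min: float = 0.05,
    both_strands_fraction: float = 0.20,
    apply_strand_filter: bool = False,
) -> KmerTable:
    """Build a filtered presence/absence table from per-individual FASTA.

    A k-mer is present in an individual when it occurs at least once in any
    of its sequences.  Filters, in order: an optional strand-support filter
    retaining k-mers observed in both orientations in at least
    ``both_strands_fraction`` of carrying individuals (meaningful for
    sequencing reads, which sample both strands; off by default because
    strand-resolved FASTA input cannot satisfy it), then a presence/absence
    "allele" filter keeping k-mers with minor allele count >= ``mac_min``
    and minor allele frequency > ``maf_min`` across individuals.
    """
    ids = list(fasta_by_individual)
    if len(ids) < 2:
        raise ValueError("need at least two individuals")
    fwd: dict[str, int] = {}
    rev: dict[str, int] = {}
    presence: dict[str, set[int]] = {}
    for col, ind in enumerate(ids):
        seen_f: set[str] = set()
        seen_r: set[str] = set()
        for seq in _iter_fasta(fasta_by_individual[ind]):
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                rc = revcomp(kmer)
                if kmer <= rc:
                    seen_f.add(kmer)
                else:
                    seen_r.add(rc)
        for km in seen_f | seen_r:
            presence.setdefault(km, set()).add(col)
        for km in seen_f:
            fwd[km] = fwd.get(km, 0) + 1
        for km in seen_r:
            rev[km] = rev.get(km, 0) + 1

    n_total = len(presence)
    kmers = sorted(presence)
    state = {"k": k, "n_kmers_raw": n_total}
    if apply_strand_filter:
        kept = []
        for km in kmers:
            carriers = len(presence[km])
            both = min(fwd.get(km, 0), rev.get(km, 0))
            if carriers and both / carriers >= both_strands_fraction:
                kept.append(km)
        state["removed_strand_filter"] = len(kmers) - len(kept)
        kmers = kept

    n_ind = len(ids)
    kept = []
    for km in kmers:
        count = len(presence[km])
        mac = min(count, n_ind - count)
        maf = mac / n_ind
        if mac >= mac_min and maf > maf_min:
            kept.append(km)
    state["removed_allele_filter"] = len(kmers) - len(kept)
    kmers = kept

    M = np.zeros((len(kmers), n_ind), dtype=bool)
    for r, km in enumerate(kmers):
        for col in presence[km]:
            M[r, col] = True
    return KmerTable(k=k, kmers=kmers, presence=M, individual_ids=ids,
                     filter_state=state)


def sample_kmer_table(t: KmerTable, n: int = 1_000_000, seed: int = 0) -> KmerTable:
    """Uniform sample of ``n`` k-mers without replacement (all, if fewer)."""
    import warnings

    if n >= t.n_kmers:
        if n > t.n_kmers:
            warnings.warn(
                f"requested {n} k-mers but table has {t.n_kmers}; returning all"
            )
        idx = np.arange(t.n_kmers)
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(t.n_kmers, size=n, replace=False))
    return KmerTable(
        k=t.k,
        kmers=[t.kmers[i] for i in idx],
        presence=t.presence[idx],
        individual_ids=t.individual_ids,
        filter_state={**t.filter_state, "sampled_n": int(idx.size), "seed": seed},
    )


def jaccard_dissimilarity(
    t: KmerTable,
    groups: dict[str, list[str]],
    n_tables: int = 100,
    table_size: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-group Jaccard dissimilarity over random k-mer sub-tables.

    The table is split into ``n_tables`` independent random sub-samples of
    ``table_size`` k-mers; within each, every within-group individual pair
    contributes 1 - |A & B| / |A | B| over the k-mers present in at least
    one of the two.  Pairs with an empty union are flagged NaN.  The result
    is the full long-format distribution; per-group means are in
    ``df.attrs['group_means']``.
    """
    col = {ind: i for i, ind in enumerate(t.individual_ids)}
    for gname, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 individuals")
        unknown = [m for m in members if m not in col]
        if unknown:
            raise ValueError(f"unknown individuals in group {gname!r}: {unknown}")
    rng = np.random.default_rng(seed)
    size = min(table_size, t.n_kmers)
    rows = []
    for tbl in range(n_tables):
        idx = rng.choice(t.n_kmers, size=size, replace=False)
        P = t.presence[idx]
        for gname, members in groups.items():
            cols = [col[m] for m in members]
            M = P[:, cols].astype(np.int64)
            inter = M.T @ M
            sizes = M.sum(axis=0)
            union = sizes[:, None] + sizes[None, :] - inter
            for a in range(len(cols)):
                for b in range(a + 1, len(cols)):
                    u = union[a, b]
                    d = 1.0 - inter[a, b] / u if u > 0 else np.nan
                    rows.append((tbl, gname, members[a], members[b], d))
    df = pd.DataFrame(rows, columns=["table", "group", "ind_a", "ind_b",
                                     "dissimilarity"])
    df.attrs["group_means"] = (
        df.groupby("group")["dissimilarity"].mean().to_dict()
    )
    return df


def kmer_matrix_for_pca(t: KmerTable) -> np.ndarray:
    """Individuals x k-mers 0/1 matrix, column order = table order."""
    if t.n_kmers == 0:
        raise ValueError("empty k-mer table")
    return t.presence.T.astype(float)
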