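"""Genotype matrices, VCF input/output and quality-control filters.

The central container is :class:`GenotypeMatrix`: diploid individuals by
biallelic loci, coded as the number of alternate alleles (0, 1, 2) with -1
for missing genotypes.  Filtering follows the usual resequencing workflow
for a multi-species panel: optional per-genotype depth masking, removal of
loci with too much missing data, removal of poorly genotyped individuals,
and a minor-allele-frequency cut-off on the retained individuals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QcThresholds",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_genotypes",
    "read_pop_labels",
]


class EmptyDataError(ValueError):
    """All rows/columns were removed or the input contained no usable sites."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-loci genotype codes.

    Parameters
    ----------
    genotypes : ndarray of int8, shape (n_individuals, n_loci)
        Count of alternate alleles per genotype; ``-1`` marks missing calls.
    chrom : ndarray of str, shape (n_loci,)
        Chromosome/contig identifier per locus.
    pos : ndarray of int, shape (n_loci,)
        1-based position per locus; strictly increasing within a chromosome.
    individual_ids : list of str
        Unique sample identifiers, one per matrix row.
    pop_labels : list of str, optional
        Population name per individual.
    depths : ndarray of int, optional
        Per-genotype sequencing depth, same shape as ``genotypes``.
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    individual_ids: list[str]
    pop_labels: list[str] | None = None
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        codes = np.unique(g)
        bad = codes[(codes < MISSING) | (codes > 2)]
        if bad.size:
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")
        if len(self.individual_ids) != g.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        if self.chrom.shape[0] != g.shape[1] or self.pos.shape[0] != g.shape[1]:
            raise ValueError("chrom/pos length mismatch")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.pop_labels is not None and len(self.pop_labels) != g.shape[0]:
            raise ValueError("pop_labels length mismatch")
        if self.depths is not None and self.depths.shape != g.shape:
            raise ValueError("depths shape mismatch")

    # -- selection -----------------------------------------------------------
    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return dataclasses.replace(
            self,
            genotypes=self.genotypes[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            depths=None if self.depths is None else self.depths[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.atleast_1d(np.asarray(index))
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return dataclasses.replace(
            self,
            genotypes=self.genotypes[idx],
            individual_ids=[self.individual_ids[i] for i in idx],
            pop_labels=None
            if self.pop_labels is None
            else [self.pop_labels[i] for i in idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def pop_index(self, pop: str) -> np.ndarray:
        """Row indices of the individuals labelled ``pop``."""
        if self.pop_labels is None:
            raise ValueError("GenotypeMatrix has no population labels")
        idx = np.array([i for i, p in enumerate(self.pop_labels) if p == pop])
        if idx.size == 0:
            raise ValueError(f"unknown population label: {pop!r}")
        return idx

    def allele_counts(self, rows: np.ndarray | None = None):
        """Per-locus (alt allele count, called haploid count)."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0)

    def missing_fraction_per_locus(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def missing_fraction_per_individual(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Minor allele frequency per locus; NaN where nothing is called."""
        alt, n = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.fmin(p, 1.0 - p)


@dataclass
class QcThresholds:
    """Genotype QC cut-offs.

    ``max_locus_missing`` drops loci missing in more than that fraction of
    individuals; ``max_indiv_missing`` drops individuals above that missing
    fraction; loci are retained only when MAF is strictly above ``maf_min``;
    ``min_genotype_depth`` masks genotypes below the depth (only when depths
    are available).
    """

    max_locus_missing: float = 0.05
    max_indiv_missing: float = 0.40
    maf_min: float = 0.05
    min_genotype_depth: int = 2

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "max_indiv_missing", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    n_loci_in: int = 0
    n_individuals_in: int = 0
    genotypes_depth_masked: int = 0
    loci_removed_missing: int = 0
    individuals_removed_missing: int = 0
    loci_removed_maf: int = 0
    n_loci_out: int = 0
    n_individuals_out: int = 0

    def check_consistency(self) -> None:
        assert (
            self.n_loci_in
            == self.n_loci_out + self.loci_removed_missing + self.loci_removed_maf
        )
        assert (
            self.n_individuals_in
            == self.n_individuals_out + self.individuals_removed_missing
        )


def filter_genotypes(
    g: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply QC filters in a fixed order and report removals.

    Order: (1) depth mask (when depths are present), (2) loci by missingness,
    (3) individuals by missingness, (4) loci by MAF computed on the retained
    individuals (strictly greater than ``maf_min`` is kept).
    """
    t = thresholds or QcThresholds()
    if g.n_loci == 0 or g.n_individuals == 0:
        raise EmptyDataError("empty genotype matrix")
    report = FilterReport(n_loci_in=g.n_loci, n_individuals_in=g.n_individuals)

    if g.depths is not None:
        masked = (g.depths < t.min_genotype_depth) & (g.genotypes != MISSING)
        report.genotypes_depth_masked = int(masked.sum())
        gt = g.genotypes.copy()
        gt[masked] = MISSING
        g = dataclasses.replace(g, genotypes=gt)

    keep_loci = g.missing_fraction_per_locus() <= t.max_locus_missing
    report.loci_removed_missing = int((~keep_loci).sum())
    g = g.take_loci(keep_loci)

    if g.n_loci > 0:
        keep_ind = g.missing_fraction_per_individual() <= t.max_indiv_missing
    else:
        keep_ind = np.ones(g.n_individuals, dtype=bool)
    report.individuals_removed_missing = int((~keep_ind).sum())
    if not keep_ind.any():
        raise EmptyDataError("all individuals removed by missingness filter")
    g = g.take_individuals(keep_ind)

    maf = g.maf()
    keep_maf = np.nan_to_num(maf, nan=0.0) > t.maf_min
    report.loci_removed_maf = int((~keep_maf).sum())
    g = g.take_loci(keep_maf)

    report.n_loci_out = g.n_loci
    report.n_individuals_out = g.n_individuals
    report.check_consistency()
    return g, report


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read genotypes from a VCF into a :class:`GenotypeMatrix`.

    Genotype codes are alternate-allele counts; ``./.`` becomes missing.
    Multi-allelic records are skipped when ``biallelic_only`` is set.  FORMAT
    ``DP`` is loaded into ``depths`` when present on every record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, chroms, positions, depths = [], [], [], []
    have_depth = True
    for var in vcf:
        if biallelic_only and (len(var.ALT) != 1 or not var.is_snp):
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3=missing
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        dp = None
        if have_depth:
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
        if dp is None:
            have_depth = False
        else:
            depths.append(np.asarray(dp, dtype=np.int32).ravel())
    vcf.close()
    if not rows:
        raise EmptyDataError(f"no biallelic SNPs found in {path}")
    return GenotypeMatrix(
        genotypes=np.array(rows, dtype=np.int8).T,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        individual_ids=ids,
        depths=np.array(depths, dtype=np.int32).T if have_depth and depths else None,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path, ref: str = "A", alt: str = "T") -> None:
    """Write a minimal VCF 4.2 with GT (and DP when depths are present).

    ``read_vcf(write_vcf(g))`` round-trips the genotype codes, coordinates
    and sample identifiers exactly.
    """
    if g.n_individuals == 0:
        raise EmptyDataError("cannot write a VCF with no samples")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fmt = "GT"
        if g.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fmt = "GT:DP"
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for j in range(g.n_loci):
            cells = []
            for i in range(g.n_individuals):
                s = _GT_STRINGS[int(g.genotypes[i, j])]
                if g.depths is not None:
                    s += f":{int(g.depths[i, j])}"
                cells.append(s)
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_pop_labels(path) -> dict[str, str]:
    """Read a two-column delimited table (individual_id, population)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"malformed label line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def attach_pop_labels(g: GenotypeMatrix, labels: dict[str, str]) -> GenotypeMatrix:
    missing = [i for i in g.individual_ids if i not in labels]
    if missing:
        raise ValueError(f"no population label for: {missing[:5]}")
    return dataclasses.replace(g, pop_labels=[labels[i] for i in g.individual_ids])
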