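"""Coalescent generator: closed-form checks, oracle agreement, determinism."""

import io

import numpy as np
import pytest
from skbio import TreeNode

import foniokit as fk
from foniokit.coalescent import simulate_genealogy
from foniokit.demographics import ModelError
from foniokit.diversity import tajimas_d_constants


def _pair_tmrca_mean(model, pop, n_reps, seed):
    rng = np.random.default_rng(seed)
    t = np.empty(n_reps)
    for r in range(n_reps):
        _, times, _ = simulate_genealogy(model, {pop: 2}, rng)
        t[r] = times[-1]
    return t.mean(), t.std() / np.sqrt(n_reps)


def test_pair_tmrca_matches_2N():
    """E[T2] = 2N generations for a constant-size population."""
    m = fk.DemographicModel(pop_names=["p"], pop_sizes={"p": 10_000.0})
    mean, se = _pair_tmrca_mean(m, "p", 20_000, seed=1)
    assert abs(mean - 20_000) / 20_000 < 0.02


def test_split_at_time_zero_is_panmictic():
    """A split at t=0 leaves one panmictic population of the ancestral size."""
    m = fk.DemographicModel(
        pop_names=["a", "b"],
        pop_sizes={"a": 1_000.0, "b": 5_000.0},
        events=[fk.Split(0.0, "a", "b"), fk.SizeChange(0.0, "b", 20_000.0)],
    )
    rng = np.random.default_rng(2)
    t = np.array([
        simulate_genealogy(m, {"a": 1, "b": 1}, rng)[1][-1]
        for _ in range(8_000)
    ])
    se = t.std() / np.sqrt(t.size)
    assert abs(t.mean() - 40_000) < 3 * se


def test_dxy_matches_divergence_expectation():
    """Mean per-site dxy ~ 2 mu (T + 2 N_anc) for an isolation model."""
    T, N = 30_000.0, 10_000.0
    m = fk.two_population_model(
        n_cultivated=N, n_wild=N, n_ancestral=N, t_div=T,
        bottleneck_size=None)
    ds = fk.simulate_unlinked_snps(m, {"cultivated": 2, "wild": 2},
                                   1_500, 1_000, seed=3)
    g = ds.genotypes
    ca, na = g.allele_counts(g.pop_index("cultivated"))
    cb, nb = g.allele_counts(g.pop_index("wild"))
    per_site = (ca * (nb - cb) + (na - ca) * cb) / (na * nb)
    # dxy over the full simulated length (monomorphic sites contribute 0)
    dxy = per_site.sum() / (1_500 * 1_000)
    expect = 2 * m.mu * (T + 2 * N)
    # locus-level dxy sums are heavy-tailed; use the empirical SE
    locus_tot = np.zeros(1_500)
    for c, tot in zip(g.chrom, per_site):
        locus_tot[int(c.split("_")[1])] += tot
    se = locus_tot.std() / np.sqrt(1_500) / 1_000
    assert abs(dxy - expect) < 3 * se


def test_watterson_and_pi_unbiased():
    """E[S] = theta a_{n-1} L and E[pi] = theta L at constant size."""
    N, L, n_loci = 10_000.0, 5_000, 10_000
    m = fk.DemographicModel(pop_names=["p"], pop_sizes={"p": N})
    ds = fk.simulate_unlinked_snps(m, {"p": 5}, n_loci, L, seed=4)
    g = ds.genotypes
    alt, called = g.allele_counts()
    theta_site = 4 * N * m.mu
    a = tajimas_d_constants(10)["a1"]
    S = g.n_loci
    expect_S = theta_site * a * L * n_loci
    assert abs(S - expect_S) / expect_S < 0.02
    pi = float((2 * alt * (called - alt) / (called * (called - 1.0))).sum())
    expect_pi = theta_site * L * n_loci
    assert abs(pi - expect_pi) / expect_pi < 0.02


def test_folded_sfs_matches_neutral_shape():
    """Folded spectrum ~ 1/i + 1/(n-i) under neutrality (chi^2 GOF)."""
    from scipy.stats import chisquare

    m = fk.DemographicModel(pop_names=["p"], pop_sizes={"p": 10_000.0})
    ds = fk.simulate_unlinked_snps(m, {"p": 5}, 4_000, 2_000, seed=6)
    sfs = fk.folded_sfs(ds.genotypes, "p", min_presence=1.0)
    n = sfs.n_haploid
    unfolded = np.zeros(n + 1)
    unfolded[1:n] = 1.0 / np.arange(1, n)
    expect = fk.sfs.fold_1d(unfolded)
    expect[0] = 0.0
    obs = sfs.counts.copy()
    obs[0] = 0.0
    expect = expect / expect.sum() * obs.sum()
    stat, p = chisquare(obs[1:], expect[1:])
    assert p > 0.001


def test_cross_oracle_msprime_agreement():
    """Mean pi, S and dxy agree with msprime under the same demography."""
    msprime = pytest.importorskip("msprime")
    n_loci, L = 500, 1_000
    m = fk.two_population_model(t_div=15_000.0)
    ds = fk.simulate_unlinked_snps(m, {"cultivated": 5, "wild": 5},
                                   n_loci, L, seed=77)
    g = ds.genotypes

    def per_locus_stats(get_counts):
        pi_c = np.zeros(n_loci)
        pi_w = np.zeros(n_loci)
        dxy = np.zeros(n_loci)
        S = np.zeros(n_loci)
        for locus, (ca, na, cb, nb) in get_counts():
            pi_c[locus] += float((2 * ca * (na - ca) / (na * (na - 1))).sum())
            pi_w[locus] += float((2 * cb * (nb - cb) / (nb * (nb - 1))).sum())
            dxy[locus] += float(((ca * (nb - cb) + (na - ca) * cb)
                                 / (na * nb)).sum())
            S[locus] += len(np.atleast_1d(ca))
        return pi_c, pi_w, dxy, S

    def ours():
        ca, na = g.allele_counts(g.pop_index("cultivated"))
        cb, nb = g.allele_counts(g.pop_index("wild"))
        for j in range(g.n_loci):
            yield int(g.chrom[j].split("_")[1]), (
                np.array([ca[j]]), na[j], np.array([cb[j]]), nb[j])

    dem = msprime.Demography()
    dem.add_population(name="cultivated", initial_size=10_000)
    dem.add_population(name="wild", initial_size=20_000)
    dem.add_population(name="anc", initial_size=20_000)
    dem.add_population_parameters_change(time=2_000, population="cultivated",
                                         initial_size=2_000)
    dem.add_population_split(time=15_000, derived=["cultivated", "wild"],
                             ancestral="anc")

    def theirs():
        reps = msprime.sim_ancestry(
            samples={"cultivated": 5, "wild": 5}, demography=dem,
            sequence_length=L, num_replicates=n_loci, random_seed=123)
        for locus, ts in enumerate(reps):
            ts = msprime.sim_mutations(ts, rate=m.mu, random_seed=locus + 1,
                                       model=msprime.BinaryMutationModel())
            G = ts.genotype_matrix()
            if G.shape[0] == 0:
                continue
            A, B = (G[:, :10] > 0), (G[:, 10:] > 0)
            yield locus, (A.sum(1), 10, B.sum(1), 10)

    ours_stats = per_locus_stats(ours)
    msp_stats = per_locus_stats(theirs)
    for a, b in zip(ours_stats, msp_stats):
        se = np.sqrt(a.var() / n_loci + b.var() / n_loci)
        assert abs(a.mean() - b.mean()) <= 3 * se


def test_bottleneck_never_increases_diversity():
    """Adding a cultivated bottleneck cannot raise expected pi."""
    with_b = fk.two_population_model(t_div=20_000.0)
    without = fk.two_population_model(t_div=20_000.0, bottleneck_size=None)
    pis = []
    for m in (with_b, without):
        ds = fk.simulate_unlinked_snps(m, {"cultivated": 4}, 1_500, 1_000,
                                       seed=9)
        alt, called = ds.genotypes.allele_counts()
        pis.append(float((2 * alt * (called - alt)
                          / (called * (called - 1.0))).sum()))
    assert pis[0] < pis[1]


class TestWindows:
    def test_count_and_coordinates(self):
        m = fk.two_population_model(t_div=5_000.0, bottleneck_size=None)
        ds = fk.simulate_windows(m, {"cultivated": 2, "wild": 2}, 100,
                                 10_000, seed=1)
        assert len(ds.windows) == 100
        starts = [w.start for w in ds.windows]
        assert starts == [i * 10_000 + 1 for i in range(100)]

    def test_same_seed_bit_identical(self):
        m = fk.four_population_model()
        kw = dict(samples={"exilis": 2, "longiflora": 2, "iburua": 2,
                           "ternata": 2}, n_windows=5, window_len=20_000)
        a = fk.simulate_windows(m, seed=42, **kw)
        b = fk.simulate_windows(m, seed=42, **kw)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert a.true_trees == b.true_trees

    def test_true_trees_group_the_pairs(self, four_pop_dataset):
        """Deep two-pair divergence: every window genealogy is pair-sorted."""
        for nwk in four_pop_dataset.true_trees:
            tree = TreeNode.read(io.StringIO(nwk), convert_underscores=False)
            tips = [t.name for t in tree.tips()]
            for pair in (("exilis", "longiflora"), ("iburua", "ternata")):
                members = [t for t in tips if t.split("_")[0] in pair]
                lca = tree.lca(members)
                assert {t.name for t in lca.tips()} == set(members) or \
                    len(list(tree.tips())) == len(members)

    def test_bad_window_length(self):
        m = fk.two_population_model()
        with pytest.raises(ValueError):
            fk.simulate_windows(m, {"cultivated": 2}, 5, 0, seed=0)


class TestSequences:
    def test_no_mutations_identical_sequences(self, tmp_path):
        m = fk.DemographicModel(pop_names=["p"], pop_sizes={"p": 100.0},
                                mu=1e-13)
        ds = fk.simulate_windows(m, {"p": 3}, 2, 2_000, seed=1)
        paths = fk.emit_sequences(ds, tmp_path)
        # within each unit, every individual/haplotype sequence is identical
        per_unit = {}
        for p in paths:
            lines = open(p).read().splitlines()
            for header, seq in zip(lines[::2], lines[1::2]):
                unit = header.split("|")[1]
                per_unit.setdefault(unit, set()).add(seq)
        assert all(len(s) == 1 for s in per_unit.values())

    def test_sequence_differences_match_haplotypes(self, tmp_path):
        from Bio import SeqIO

        m = fk.two_population_model(t_div=50_000.0, bottleneck_size=None)
        ds = fk.simulate_windows(m, {"cultivated": 2, "wild": 2}, 3, 5_000,
                                 seed=8)
        paths = fk.emit_sequences(ds, tmp_path)
        seqs = {}
        for p in paths:
            for rec in SeqIO.parse(str(p), "fasta"):
                ind, unit, hap = rec.id.split("|")
                seqs[(ind, unit, hap)] = str(rec.seq)
        ids = ds.genotypes.individual_ids
        for u, (pos, H) in enumerate(ds.haplotypes):
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    for hi in (0, 1):
                        for hj in (0, 1):
                            a = seqs[(ids[i], f"unit{u}", f"hap{hi}")]
                            b = seqs[(ids[j], f"unit{u}", f"hap{hj}")]
                            ham = sum(x != y for x, y in zip(a, b))
                            expect = int((H[2 * i + hi] != H[2 * j + hj]).sum())
                            assert ham == expect

    def test_requires_haplotypes(self):
        ds = fk.SimulatedDataset(
            genotypes=fk.simulate_unlinked_snps(
                fk.two_population_model(), {"cultivated": 2, "wild": 2},
                3, 500, seed=1).genotypes,
            seed=1, haplotypes=None)
        with pytest.raises(ValueError):
            fk.emit_sequences(ds, "/tmp/nowhere")


class TestMissingness:
    def test_rate_zero_identity(self, two_pop_split_dataset):
        g = two_pop_split_dataset.genotypes
        out = fk.inject_missingness(g, rate=0.0, seed=1)
        assert np.array_equal(out.genotypes, g.genotypes)

    def test_rate_one_all_missing(self, two_pop_split_dataset):
        out = fk.inject_missingness(two_pop_split_dataset.genotypes,
                                    rate=1.0, seed=1)
        assert np.all(out.genotypes == -1)

    def test_rate_within_binomial_tolerance(self, two_pop_split_dataset):
        g = two_pop_split_dataset.genotypes
        out = fk.inject_missingness(g, rate=0.1, seed=3)
        frac = (out.genotypes == -1).mean()
        assert abs(frac - 0.1) < 0.01

    def test_bad_rate(self, two_pop_split_dataset):
        with pytest.raises(ValueError):
            fk.inject_missingness(two_pop_split_dataset.genotypes, rate=1.5)


def test_unjoinable_model_rejected():
    with pytest.raises(ModelError):
        fk.DemographicModel(
            pop_names=["a", "b"],
            pop_sizes={"a": 100.0, "b": 100.0},
            events=[],  # two populations that never merge
        )
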