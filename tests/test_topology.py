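"""Window NJ trees, topology weighting and drift covariance trees."""

import numpy as np
import pandas as pd
import pytest

import foniokit as fk
from foniokit.diversity import WindowSpec
from foniokit.topology import (
    WindowTree,
    allele_freq_covariance,
    bootstrap_tree,
    fit_population_tree,
    twisst_weights,
    window_nj_trees,
)
from conftest import make_genotypes


def _tree_distances(n_tips, rng):
    """Random rooted binary tree; return additive tip distances + splits."""
    # represent trees as (left, right); leaves are ints
    leaves = list(range(n_tips))
    rng.shuffle(leaves)
    items = [(lv,) for lv in leaves]

    def build(items):
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), 2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            items.append((a, b))
        return items[0]

    shape = build(items)
    # assign branch lengths per edge, collect leafsets and path distances
    D = np.zeros((n_tips, n_tips))
    splits = []

    def walk(t):
        """Return {leaf: distance to this node's root}."""
        if len(t) == 1:
            return {t[0]: 0.0}
        left, right = t
        dl = walk(left)
        dr = walk(right)
        bl = rng.uniform(0.2, 1.5)
        br = rng.uniform(0.2, 1.5)
        for x, dx in dl.items():
            for y, dy in dr.items():
                D[x, y] = D[y, x] = dx + bl + dy + br
        if len(dl) > 1:
            splits.append(frozenset(dl))
        if len(dr) > 1:
            splits.append(frozenset(dr))
        return {**{x: d + bl for x, d in dl.items()},
                **{y: d + br for y, d in dr.items()}}

    walk(shape)
    return D, splits


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_nj_recovers_additive_trees(seed):
    """NJ is consistent on exactly additive distances (random trees)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    D, true_splits = _tree_distances(n, rng)
    ids = [f"t{i}" for i in range(n)]
    tree = nj(DistanceMatrix(D, ids=ids))
    everyone = frozenset(range(n))
    got = set()
    for node in tree.non_tips():
        clade = frozenset(int(t.name[1:]) for t in node.tips())
        if 2 <= len(clade) <= n - 2:
            got.add(min(clade, everyone - clade,
                        key=lambda s: (len(s), sorted(s))))
    want = set()
    for s in true_splits:
        if 2 <= len(s) <= n - 2:
            want.add(min(s, everyone - s, key=lambda s2: (len(s2), sorted(s2))))
    assert want <= got


class TestWindowTrees:
    def test_windows_without_snps_skipped(self):
        g = make_genotypes(np.array([[0, 1], [1, 0], [2, 1], [0, 2]],
                                    dtype=np.int8),
                           pos=[10, 120_000])
        trees = window_nj_trees(g, w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=1)
        assert all(t.n_snps >= 1 for t in trees)
        starts = {t.start for t in trees}
        assert 50_001 not in starts  # empty middle window skipped

    def test_duplicated_individual_zero_terminal_pair(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        codes[1] = codes[0]
        g = make_genotypes(codes, pos=np.arange(1, 31) * 10)
        trees = window_nj_trees(g, w=WindowSpec(1_000, 1_000),
                                min_snps_per_window=5)
        t = trees[0].tree()
        a = t.find("i0")
        b = t.find("i1")
        assert a.parent is b.parent
        assert (a.length or 0) + (b.length or 0) == pytest.approx(0, abs=1e-9)

    def test_deep_pairs_resolved(self, four_pop_dataset):
        trees = window_nj_trees(four_pop_dataset.genotypes,
                                w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=5)
        assert len(trees) == 25


class TestTwisst:
    def test_single_tip_per_group_exact(self):
        wt = WindowTree("1", 1, 100, "((a:1,b:1):1,(c:1,d:1):1);", 10)
        df = twisst_weights([wt], {"A": ["a"], "B": ["b"], "C": ["c"],
                                   "D": ["d"]})
        assert df.loc[0, "w_T1"] == 1.0
        assert df.loc[0, "w_T2"] == 0.0

    def test_weights_sum_to_one(self, four_pop_dataset):
        g = four_pop_dataset.genotypes
        trees = window_nj_trees(g, w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=5)
        groups = {p: [i for i, q in zip(g.individual_ids, g.pop_labels)
                      if q == p]
                  for p in ("exilis", "longiflora", "iburua", "ternata")}
        df = twisst_weights(trees, groups, method="exact")
        sums = df[["w_T1", "w_T2", "w_T3"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_deep_two_pair_supports_paired_topology(self, four_pop_dataset):
        g = four_pop_dataset.genotypes
        trees = window_nj_trees(g, w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=5)
        groups = {p: [i for i, q in zip(g.individual_ids, g.pop_labels)
                      if q == p]
                  for p in ("exilis", "longiflora", "iburua", "ternata")}
        df = twisst_weights(trees, groups, method="exact")
        frac = df.attrs["max_weight_fraction"][
            "((exilis,longiflora),(iburua,ternata))"]
        assert frac == 1.0

    def test_panmixia_gives_uniform_mean_weights(self):
        """Arbitrary groups in one panmictic population: weights ~ 1/3."""
        m = fk.DemographicModel(pop_names=["p"], pop_sizes={"p": 10_000.0})
        ds = fk.simulate_windows(m, {"p": 8}, 60, 50_000, seed=17)
        g = ds.genotypes
        ids = g.individual_ids
        groups = {"A": ids[:2], "B": ids[2:4], "C": ids[4:6], "D": ids[6:]}
        trees = window_nj_trees(g, w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=3)
        df = twisst_weights(trees, groups, method="exact")
        means = df.attrs["mean_weights"]
        for v in means.values():
            assert abs(v - 1 / 3) < 0.12

    def test_sampled_agrees_with_exact(self, four_pop_dataset):
        g = four_pop_dataset.genotypes
        trees = window_nj_trees(g, w=WindowSpec(50_000, 50_000),
                                min_snps_per_window=5)[:5]
        groups = {p: [i for i, q in zip(g.individual_ids, g.pop_labels)
                      if q == p]
                  for p in ("exilis", "longiflora", "iburua", "ternata")}
        exact = twisst_weights(trees, groups, method="exact")
        sampled = twisst_weights(trees, groups, method="sampled",
                                 max_subsamples=300, seed=3)
        for col in ("w_T1", "w_T2", "w_T3"):
            p = exact[col].mean()
            se = max(np.sqrt(p * (1 - p) / 300), 1e-3)
            assert abs(sampled[col].mean() - p) <= 3 * se

    def test_missing_group_excluded(self):
        wt = WindowTree("1", 1, 100, "((a:1,b:1):1,(c:1,d:1):1);", 10)
        df = twisst_weights([wt], {"A": ["a"], "B": ["b"], "C": ["c"],
                                   "D": ["zz"]})
        assert df.loc[0, "method"] == "excluded"
        assert df.attrs["n_windows_used"] == 0

    def test_requires_four_groups(self):
        with pytest.raises(ValueError):
            twisst_weights([], {"A": ["a"], "B": ["b"]})


class TestCovariance:
    def test_symmetric(self, four_pop_dataset):
        W = allele_freq_covariance(four_pop_dataset.genotypes,
                                   ["exilis", "longiflora", "iburua",
                                    "ternata"])
        assert np.allclose(W, W.T)

    def test_identical_populations_covary_like_themselves(self):
        # pop B duplicates pop A's individuals; with real drift against an
        # outgroup C, cov(A, B) matches var(A) up to the diagonal
        # sampling-bias correction (applied to the diagonal only)
        model = fk.two_population_model(t_div=100_000.0,
                                        bottleneck_size=None)
        ds = fk.simulate_unlinked_snps(model, {"cultivated": 6, "wild": 6},
                                       400, 1_000, seed=31)
        base = ds.genotypes
        codes = np.vstack([base.genotypes[:6], base.genotypes[:6],
                           base.genotypes[6:]])
        g = make_genotypes(codes, pops=["A"] * 6 + ["B"] * 6 + ["C"] * 6,
                           pos=list(range(10, 10 * base.n_loci + 10, 10)))
        W = allele_freq_covariance(g, ["A", "B", "C"])
        assert W.loc["A", "B"] == pytest.approx(
            (W.loc["A", "A"] + W.loc["B", "B"]) / 2, rel=0.2)
        assert W.loc["A", "B"] > W.loc["A", "C"]

    def test_star_tree_matches_centering_projection(self):
        """Equal drift on a star tree: W ~ c (I - 11'/k)."""
        model = fk.DemographicModel(
            pop_names=["a", "b", "c", "d"],
            pop_sizes={p: 5_000.0 for p in "abcd"},
            events=[fk.Split(8_000.0, p, "a") for p in "bcd"]
            + [fk.SizeChange(8_000.0, "a", 5_000.0)],
        )
        ds = fk.simulate_unlinked_snps(model, {p: 6 for p in "abcd"},
                                       3_000, 1_000, seed=23)
        W = allele_freq_covariance(ds.genotypes, list("abcd")).to_numpy()
        A = np.eye(4) - np.ones((4, 4)) / 4
        c = np.trace(W) / np.trace(A)
        resid = np.abs(W - c * A).max()
        assert resid < 0.15 * c

    def test_all_missing_population_rejected(self):
        codes = np.array([[0, 1], [-1, -1]], dtype=np.int8)
        g = make_genotypes(codes, pops=["A", "B"])
        with pytest.raises(ValueError):
            allele_freq_covariance(g, ["A", "B"])


def _exact_w(clade_lengths, pops):
    P = len(pops)
    idx = {p: i for i, p in enumerate(pops)}
    V = np.zeros((P, P))
    for cl, ell in clade_lengths.items():
        members = [idx[p] for p in cl]
        V[np.ix_(members, members)] += ell
    A = np.eye(P) - np.ones((P, P)) / P
    return A @ V @ A


class TestFitPopulationTree:
    CLADES = {
        frozenset("a"): 0.3, frozenset("b"): 0.2, frozenset("c"): 0.25,
        frozenset("d"): 0.15, frozenset(["a", "b"]): 0.5,
        frozenset(["c", "d"]): 0.4,
    }

    def test_noiseless_inverse_recovery(self):
        W = _exact_w(self.CLADES, list("abcd"))
        fit = fit_population_tree(W, pops=list("abcd"))
        assert fit.variance_explained == pytest.approx(1.0, abs=1e-9)
        assert frozenset(["a", "b"]) in fit.branch_lengths or \
            frozenset(["c", "d"]) in fit.branch_lengths

    def test_population_order_invariance(self):
        W = _exact_w(self.CLADES, list("abcd"))
        fit1 = fit_population_tree(W, pops=list("abcd"))
        perm = [2, 0, 3, 1]
        Wp = W[np.ix_(perm, perm)]
        fit2 = fit_population_tree(Wp, pops=[list("abcd")[i] for i in perm])
        s1 = {cl for cl in fit1.branch_lengths if len(cl) == 2}
        s2 = {cl for cl in fit2.branch_lengths if len(cl) == 2}
        # same unrooted split structure up to complements
        every = frozenset("abcd")
        canon = lambda ss: {min(c, every - c, key=sorted) for c in ss}
        assert canon(s1) == canon(s2)
        assert fit1.variance_explained == pytest.approx(
            fit2.variance_explained, abs=1e-9)

    def test_scale_equivariance(self):
        W = _exact_w(self.CLADES, list("abcd"))
        f1 = fit_population_tree(W, pops=list("abcd"))
        f3 = fit_population_tree(3.0 * W, pops=list("abcd"))
        assert set(f3.branch_lengths) == set(f1.branch_lengths)
        for cl, ell in f1.branch_lengths.items():
            assert f3.branch_lengths[cl] == pytest.approx(3 * ell, abs=1e-8)
        assert np.allclose(f3.W_hat, 3 * f1.W_hat, atol=1e-8)

    def test_two_pair_simulation_high_variance_explained(self,
                                                         four_pop_dataset):
        W = allele_freq_covariance(
            four_pop_dataset.genotypes,
            ["exilis", "longiflora", "iburua", "ternata"])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_population_tree(W)
        assert fit.variance_explained > 0.999
        assert frozenset(["exilis", "longiflora"]) in fit.branch_lengths or \
            frozenset(["iburua", "ternata"]) in fit.branch_lengths

    def test_too_many_populations(self):
        with pytest.raises(ValueError):
            fit_population_tree(np.eye(7), pops=list("abcdefg"))


class TestBootstrap:
    def test_single_replicate_matches_single_fit(self, four_pop_dataset):
        import warnings

        g = four_pop_dataset.genotypes
        pops = ["exilis", "longiflora", "iburua", "ternata"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cons, supp = bootstrap_tree(g, pops,
                                        block_size=g.n_loci // 4,
                                        n_boot=1, seed=5)
        assert all(v in (0.0, 1.0) for v in supp.values())

    def test_same_seed_identical(self, four_pop_dataset):
        import warnings

        g = four_pop_dataset.genotypes
        pops = ["exilis", "longiflora", "iburua", "ternata"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = bootstrap_tree(g, pops, block_size=g.n_loci // 6,
                                n_boot=6, seed=7)
            r2 = bootstrap_tree(g, pops, block_size=g.n_loci // 6,
                                n_boot=6, seed=7)
        assert r1 == r2

    def test_strong_signal_full_support(self, four_pop_dataset):
        import warnings

        g = four_pop_dataset.genotypes
        pops = ["exilis", "longiflora", "iburua", "ternata"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cons, supp = bootstrap_tree(g, pops, block_size=g.n_loci // 10,
                                        n_boot=20, seed=3)
        pair = supp.get(frozenset(["iburua", "ternata"]), 0.0)
        assert pair == 1.0
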