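"""Composite-likelihood demographic inference: expectations, optimiser,
model comparison and bootstrap."""

import numpy as np
import pandas as pd
import pytest

import foniokit as fk
from foniokit.demography import (
    PAIR_PRIORS_DEFAULT,
    Prior,
    SFSDemographyModel,
    compare_models,
    composite_log_likelihood,
    expected_sfs,
    pair_model_factory,
    parametric_bootstrap,
    simulate_sfs_counts,
)
from foniokit.sfs import FoldedSFS


def _one_pop(n=10_000.0):
    return fk.DemographicModel(pop_names=["p"], pop_sizes={"p": n})


class TestExpectedSfs:
    def test_neutral_folded_closed_form(self):
        # n = 4 haploids: unfolded xi_i ~ 1/i; folded (eta1, eta2)
        # = (1 + 1/3, 1/2) / (11/6) = (8/11, 3/11)
        props = expected_sfs(_one_pop(), {"p": 2}, n_sims=30_000, seed=3)
        eta = props[("p", "p")]
        assert eta[1] == pytest.approx(8 / 11, abs=0.01)
        assert eta[2] == pytest.approx(3 / 11, abs=0.01)

    def test_proportions_sum_to_one(self):
        m = fk.two_population_model()
        props = expected_sfs(m, {"cultivated": 4, "wild": 3}, n_sims=2_000,
                             seed=1)
        for p in props.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.flat[0] == 0.0

    def test_split_at_zero_equals_panmixia(self):
        """Joint SFS right after a split rearranges the panmictic SFS."""
        m = fk.DemographicModel(
            pop_names=["a", "b"], pop_sizes={"a": 7_000.0, "b": 9_000.0},
            events=[fk.Split(0.0, "a", "b"),
                    fk.SizeChange(0.0, "b", 10_000.0)])
        joint = expected_sfs(m, {"a": 2, "b": 2}, n_sims=30_000,
                             seed=2)[("a", "b")]
        # pooled minor-allele-count spectrum from the joint SFS
        pooled = np.zeros(5)
        na, nb = 4, 4
        for i in range(na + 1):
            for j in range(nb + 1):
                pooled[min(i + j, 8 - i - j)] += joint[i, j]
        single = expected_sfs(_one_pop(), {"p": 4}, n_sims=30_000,
                              seed=4)[("p", "p")]
        assert np.allclose(pooled[1:], single[1:], atol=0.01)

    def test_monte_carlo_error_shrinks(self):
        errs = {n: [] for n in (200, 3_200)}
        for n_sims in errs:
            for s in range(10):
                eta = expected_sfs(_one_pop(), {"p": 2}, n_sims=n_sims,
                                   seed=100 + s)[("p", "p")]
                errs[n_sims].append(abs(eta[1] - 8 / 11))
        assert np.mean(errs[200]) > 2 * np.mean(errs[3_200])

    def test_mutation_mode_agrees_with_branch_mode(self):
        branch = expected_sfs(_one_pop(), {"p": 3}, n_sims=20_000, seed=5,
                              mode="branch")[("p", "p")]
        mut = expected_sfs(_one_pop(), {"p": 3}, n_sims=20_000, seed=6,
                           mode="mutation", locus_len=10_000)[("p", "p")]
        assert np.allclose(branch[1:], mut[1:], atol=0.02)


class TestCompositeLogLikelihood:
    def test_uniform_expected_arithmetic(self):
        obs = np.array([0.0, 10, 10, 10])
        e = np.array([0.0, 1, 1, 1]) / 3
        assert composite_log_likelihood(obs, e) == pytest.approx(
            30 * np.log(1 / 3))

    def test_multinomial_maximum_at_proportionality(self):
        rng = np.random.default_rng(0)
        e = rng.random(6)
        e[0] = 0
        e = e / e.sum()
        obs = 1000 * e
        best = composite_log_likelihood(obs, e)
        for _ in range(20):
            q = rng.random(6)
            q[0] = 0
            q /= q.sum()
            assert composite_log_likelihood(obs, q) <= best + 1e-9

    def test_consistent_permutation_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(0, 50, 8).astype(float)
        e = rng.random(8)
        e /= e.sum()
        perm = np.concatenate([[0], 1 + rng.permutation(7)])
        assert composite_log_likelihood(obs[perm], e[perm]) == pytest.approx(
            composite_log_likelihood(obs, e))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            composite_log_likelihood(np.ones(4), np.ones(5) / 5)


def _toy_model(n_true=10_000.0, seed=11, n_sites=2_000_000):
    """One population; estimate N from its folded SFS.

    Invariant sites are included: the folded *proportions* of a
    constant-size population are free of N (the 1/i shape), so absolute
    size only becomes identifiable through the polymorphic fraction.
    """
    factory = lambda p: _one_pop(p["N"])
    obs = simulate_sfs_counts(_one_pop(n_true), {"p": 10}, n_sites,
                              pairs=[("p", "p")], seed=seed,
                              polymorphic_only=False)
    priors = {"N": Prior("loguniform", 500, 200_000)}
    return SFSDemographyModel(obs, factory, priors, {"p": 10},
                              model_id="one_pop", include_monomorphic=True)


class TestOptimizer:
    def test_single_parameter_recovery(self):
        model = _toy_model()
        res = model.fit(cycles=15, proposals_per_cycle=6, n_sims=10_000,
                        seed=3)
        assert res.params["N"] == pytest.approx(10_000, rel=0.10)

    def test_zero_cycles_returns_best_initial_proposal(self):
        model = _toy_model()
        res = model.fit(cycles=0, proposals_per_cycle=4, n_sims=1_000, seed=5)
        assert len(res.trajectory) == 1
        assert np.isfinite(res.lnl)

    def test_same_seed_identical(self):
        model = _toy_model()
        a = model.fit(cycles=4, proposals_per_cycle=3, n_sims=1_000, seed=9)
        b = model.fit(cycles=4, proposals_per_cycle=3, n_sims=1_000, seed=9)
        assert a.params.equals(b.params)
        assert a.lnl == b.lnl

    def test_aic_identity(self):
        model = _toy_model()
        res = model.fit(cycles=2, proposals_per_cycle=3, n_sims=1_000, seed=1)
        assert res.aic == 2 * res.n_parameters - 2 * res.lnl

    def test_trajectory_monotone(self):
        model = _toy_model()
        res = model.fit(cycles=8, proposals_per_cycle=4, n_sims=2_000, seed=2)
        lnls = [v for _, v in res.trajectory]
        assert all(b >= a for a, b in zip(lnls, lnls[1:]))

    def test_init_values_seed_the_incumbent(self):
        model = _toy_model()
        res = model.fit(cycles=0, proposals_per_cycle=0, n_sims=2_000,
                        seed=4, init_values={"N": 10_000.0})
        assert res.params["N"] == 10_000.0

    def test_summary_mentions_years(self):
        model = _toy_model()
        res = model.fit(cycles=0, proposals_per_cycle=2, n_sims=500, seed=1)
        assert "composite lnL" in res.summary()


class TestPriors:
    def test_validation(self):
        with pytest.raises(ValueError):
            Prior("uniform", 5, 5)
        with pytest.raises(ValueError):
            Prior("loguniform", 0, 10)
        with pytest.raises(ValueError):
            Prior("normal", 0, 1)

    def test_sampling_within_bounds(self):
        rng = np.random.default_rng(0)
        p = Prior("loguniform", 10, 1_000)
        draws = [p.sample(rng) for _ in range(200)]
        assert min(draws) >= 10 and max(draws) <= 1_000


class TestModelComparison:
    def test_identical_models_equal_within_noise(self):
        obs = simulate_sfs_counts(_one_pop(), {"p": 8}, 5_000,
                                  pairs=[("p", "p")], seed=2)
        factory = lambda p: _one_pop(p["N"])
        priors = {"N": Prior("loguniform", 1_000, 100_000)}
        m1 = SFSDemographyModel(obs, factory, priors, {"p": 8},
                                model_id="copy1")
        m2 = SFSDemographyModel(obs, factory, priors, {"p": 8},
                                model_id="copy2")
        table, _ = compare_models([m1, m2], seed=3, cycles=6,
                                  proposals_per_cycle=4, n_sims=3_000)
        lnls = table["lnl"].to_numpy()
        assert abs(lnls[0] - lnls[1]) < 0.002 * abs(lnls).max()

    def test_singleton_set_trivially_ranked(self):
        model = _toy_model()
        with pytest.warns(UserWarning):
            table, res = compare_models([model], seed=1, cycles=1,
                                        proposals_per_cycle=2, n_sims=500)
        assert table.loc[0, "delta_aic"] == 0.0


class TestParametricBootstrap:
    def _fitted(self):
        model = _toy_model()
        return model.fit(cycles=6, proposals_per_cycle=4, n_sims=4_000,
                         seed=3)

    def test_single_dataset_degenerate_ci(self):
        res = self._fitted()
        ci = parametric_bootstrap(res, n_datasets=1, seed=5, cycles=2,
                                  proposals_per_cycle=2, n_sims=1_000,
                                  sim_n_sims=4_000)
        assert ci.loc["N", "ci_low"] == ci.loc["N", "ci_high"]
        assert not ci.attrs["reliable"]

    def test_same_seed_identical(self):
        res = self._fitted()
        kw = dict(n_datasets=3, seed=7, cycles=2, proposals_per_cycle=2,
                  n_sims=1_000, sim_n_sims=4_000)
        c1 = parametric_bootstrap(res, **kw)
        c2 = parametric_bootstrap(res, **kw)
        assert c1.equals(c2)

    def test_interval_brackets_point_sanely(self):
        res = self._fitted()
        ci = parametric_bootstrap(res, n_datasets=6, seed=9, cycles=3,
                                  proposals_per_cycle=3, n_sims=2_000,
                                  sim_n_sims=6_000)
        assert ci.loc["N", "ci_low"] <= ci.loc["N", "median"] <= \
            ci.loc["N", "ci_high"]


def test_pair_factory_and_default_priors_cover_parameters():
    factory = pair_model_factory(True)
    params = {k: PAIR_PRIORS_DEFAULT[k].low for k in PAIR_PRIORS_DEFAULT}
    params.update(N_CULT=5_000, N_WILD=5_000, N_ANC=5_000,
                  T_DIV=10_000, N_BOT=500, T_EXP=1_000)
    m = factory(params)
    assert set(m.pop_sizes) == {"cultivated", "wild"}
    assert any(isinstance(e, fk.Bottleneck) for e in m.events)
    m2 = pair_model_factory(False)(params)
    assert not any(isinstance(e, fk.Bottleneck) for e in m2.events)
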