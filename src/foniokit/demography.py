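"""SFS-based coalescent demographic inference and model comparison.

The engine follows the fastsimcoal recipe: the expected folded joint
site-frequency spectrum of each population pair under a candidate
demography is estimated from coalescent simulations (branch-length
weighting by default), a composite log-likelihood treats observed SFS
classes as multinomial counts under those expected proportions, parameters
are searched with a cycle-based stochastic optimiser (re-centre and shrink
the search ranges after a run of non-improving cycles), models are ranked
by AIC, and confidence intervals come from a parametric bootstrap.

:class:`SFSDemographyModel` is the model object (observed spectra + a
demography factory + priors); :meth:`SFSDemographyModel.fit` returns a
:class:`DemographyResults` with the point estimates, the maximum composite
log-likelihood, the AIC and the search trajectory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .demographics import DemographicModel, two_population_model
from .sfs import FoldedSFS, JointFoldedSFS, fold_1d, fold_joint

__all__ = [
    "Prior",
    "expected_sfs",
    "simulate_sfs_counts",
    "composite_log_likelihood",
    "SFSDemographyModel",
    "DemographyResults",
    "compare_models",
    "parametric_bootstrap",
    "pair_model_factory",
    "PAIR_PRIORS_DEFAULT",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Prior:
    """Search range for one parameter: uniform or log-uniform on [low, high]."""

    dist: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError("dist must be 'uniform' or 'loguniform'")
        if not self.low < self.high:
            raise ValueError("prior requires low < high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform prior requires low > 0")

    def sample(self, rng: np.random.Generator, low=None, high=None) -> float:
        lo = self.low if low is None else low
        hi = self.high if high is None else high
        if self.dist == "loguniform":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# Expected SFS and composite likelihood
# ---------------------------------------------------------------------------

def _kernel_inputs(model: DemographicModel, samples: dict[str, int]):
    idx, sizes0, ev_time, ev_kind, ev_a, ev_b = model.compile_events()
    n_slots = sizes0.shape[0]
    hap = np.zeros(n_slots, dtype=np.int64)
    for p, k in samples.items():
        if p not in idx:
            raise ValueError(f"unknown population {p!r}")
        hap[idx[p]] = 2 * int(k)
    return idx, hap, sizes0, ev_time, ev_kind, ev_a, ev_b


def expected_sfs(
    model: DemographicModel,
    samples: dict[str, int],
    pairs: list[tuple[str, str]] | None = None,
    n_sims: int = 5000,
    seed: int = 1,
    mode: str = "branch",
    locus_len: int = 1000,
    polymorphic_only: bool = True,
):
    """Monte-Carlo expected folded SFS proportions per population pair.

    ``samples`` gives diploid counts.  For a pair (a, b) the result is a
    folded joint matrix of proportions over polymorphic classes (the
    monomorphic (0, 0) class is removed and the rest normalised to one);
    a "pair" (a, a) yields the 1-D folded spectrum of population a.

    With ``polymorphic_only=False`` the result is instead the per-site
    class probability under the infinite-sites model — mu times the
    expected branch length per class, with the remainder in the
    monomorphic (0, 0) entry.  Including invariant sites this way makes
    absolute population sizes identifiable from a single spectrum.

    ``mode='branch'`` weights frequency classes by expected branch length
    (low variance); ``mode='mutation'`` drops Poisson mutations per
    genealogy at rate ``mu * locus_len`` and counts them, which is noisier
    but mirrors data generation exactly.
    """
    if n_sims < 10:
        raise ValueError("n_sims too small for a meaningful estimate")
    if pairs is None:
        sampled = [p for p, k in samples.items() if k > 0]
        if len(sampled) == 1:
            pairs = [(sampled[0], sampled[0])]
        else:
            pairs = [
                (a, b)
                for i, a in enumerate(sampled)
                for b in sampled[i + 1:]
            ]
    idx, hap, sizes0, ev_time, ev_kind, ev_a, ev_b = _kernel_inputs(model, samples)
    n_slots = sizes0.shape[0]
    pair_i = np.array([idx[a] for a, _ in pairs], dtype=np.int64)
    pair_j = np.array([idx[b] for _, b in pairs], dtype=np.int64)
    max_a = int(hap[pair_i].max())
    max_b = int(hap[pair_j].max())
    W = np.zeros((len(pairs), max_a + 1, max_b + 1))
    theta = model.mu * locus_len
    total = _kernel.sim_joint_branch_weights(
        n_slots, hap, sizes0, ev_time, ev_kind, ev_a, ev_b,
        int(n_sims), int(seed) % (2**31 - 1) or 1,
        pair_i, pair_j, W, theta, mode == "mutation",
    )
    if total < 0:
        from .demographics import ModelError

        raise ModelError("remaining lineages can never coalesce; check splits")
    out = {}
    for k, (a, b) in enumerate(pairs):
        na, nb = int(hap[pair_i[k]]), int(hap[pair_j[k]])
        block = W[k, : na + 1, : nb + 1]
        if a == b:
            diag = np.array([block[c, c] for c in range(na + 1)])
            folded = fold_1d(diag)
        else:
            folded = fold_joint(block)
        folded = folded.copy()
        folded.flat[0] = 0.0
        s = folded.sum()
        if s <= 0:
            raise ValueError("degenerate model: no polymorphic mass")
        if polymorphic_only:
            out[(a, b)] = folded / s
        else:
            if mode == "mutation":
                raise ValueError("per-site probabilities require branch mode")
            per_site = folded * model.mu / n_sims
            total_poly = per_site.sum()
            if total_poly >= 1.0:
                raise ValueError("mutation rate too high for per-site model")
            per_site.flat[0] = 1.0 - total_poly
            out[(a, b)] = per_site
    return out


def simulate_sfs_counts(
    model: DemographicModel,
    samples: dict[str, int],
    n_sites,
    pairs: list[tuple[str, str]] | None = None,
    seed: int = 1,
    n_sims: int = 40_000,
    polymorphic_only: bool = True,
):
    """Simulate observed folded SFS counts of unlinked sites.

    Unlinked sites are i.i.d. draws from the single-site class
    distribution, so counts are multinomial over the expected proportions
    (estimated at ``n_sims`` genealogies).  ``n_sites`` may be an int or a
    per-pair dict; with ``polymorphic_only=False`` it counts all sites and
    the monomorphic class receives its share.  Returns
    :class:`FoldedSFS`/:class:`JointFoldedSFS` objects keyed by pair.
    """
    rng = np.random.default_rng(seed)
    props = expected_sfs(model, samples, pairs=pairs, n_sims=n_sims,
                         seed=int(rng.integers(1, 2**31 - 1)),
                         polymorphic_only=polymorphic_only)
    out = {}
    for pair, p in props.items():
        n = n_sites[pair] if isinstance(n_sites, dict) else int(n_sites)
        counts = rng.multinomial(n, p.ravel()).reshape(p.shape).astype(float)
        if pair[0] == pair[1]:
            out[pair] = FoldedSFS(counts=counts,
                                  n_haploid=2 * samples[pair[0]], pop=pair[0])
        else:
            out[pair] = JointFoldedSFS(matrix=counts, pops=pair)
    return out


def _counts_of(obs) -> np.ndarray:
    if isinstance(obs, FoldedSFS):
        return np.asarray(obs.counts, dtype=float)
    if isinstance(obs, JointFoldedSFS):
        return np.asarray(obs.matrix, dtype=float)
    return np.asarray(obs, dtype=float)


def composite_log_likelihood(observed, expected, eps: float = _EPS,
                             include_monomorphic: bool = False) -> float:
    """Sum over pairs/classes of obs * ln(expected proportion).

    ``observed`` and ``expected`` are dicts with matching keys (or single
    arrays); monomorphic classes (flat index 0) are excluded unless
    ``include_monomorphic`` (for expectations that carry invariant-site
    probabilities); expected proportions are floored at ``eps``.
    """
    if not isinstance(observed, dict):
        observed = {"_": observed}
        expected = {"_": expected}
    if set(observed) != set(expected):
        raise ValueError("observed/expected key mismatch")
    start = 0 if include_monomorphic else 1
    lnl = 0.0
    for key, obs in observed.items():
        o = _counts_of(obs).ravel()
        e = np.asarray(expected[key], dtype=float).ravel()
        if o.shape != e.shape:
            raise ValueError(f"dimension mismatch for {key}")
        o = o[start:]
        e = np.maximum(e[start:], eps)
        lnl += float(np.sum(o * np.log(e)))
    return lnl


# ---------------------------------------------------------------------------
# Model object and optimiser
# ---------------------------------------------------------------------------

@dataclass
class DemographyResults:
    """Point estimates and fit diagnostics for one demographic model."""

    model_id: str
    params: pd.Series
    lnl: float
    n_parameters: int
    trajectory: list
    seed: int
    gen_time_years: float = 1.0
    n_sims: int = 0
    model: "SFSDemographyModel | None" = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.lnl

    def summary(self) -> str:
        lines = [
            f"Demographic model: {self.model_id}",
            f"composite lnL: {self.lnl:.3f}   parameters: {self.n_parameters}"
            f"   AIC: {self.aic:.3f}",
            "parameter estimates:",
        ]
        for name, v in self.params.items():
            extra = ""
            if name.startswith("T_"):
                extra = f"  ({v * self.gen_time_years:,.0f} years)"
            lines.append(f"  {name:>10s} = {v:,.6g}{extra}")
        return "\n".join(lines)

    def expected(self, n_sims: int | None = None, seed: int | None = None):
        if self.model is None:
            raise ValueError("results are detached from their model")
        return self.model.expected(dict(self.params),
                                   n_sims=n_sims or max(self.n_sims, 1000),
                                   seed=self.seed if seed is None else seed)


class SFSDemographyModel:
    """Composite-likelihood demographic model for folded SFS data.

    Parameters
    ----------
    observed : dict[(popA, popB) -> JointFoldedSFS/FoldedSFS] or a single
        spectrum (keyed as a one-population model).
    factory : callable(params: dict) -> DemographicModel
        Builds the demography from a parameter dictionary.
    priors : dict[str, Prior]
        Search range per free parameter.
    samples : dict[str, int]
        Diploid sample sizes per population.
    fixed_params : dict, optional
        Parameters passed to the factory but not searched.
    """

    def __init__(self, observed, factory, priors: dict[str, Prior],
                 samples: dict[str, int], fixed_params: dict | None = None,
                 model_id: str = "model", include_monomorphic: bool = False):
        if isinstance(observed, FoldedSFS):
            observed = {(observed.pop, observed.pop): observed}
        elif isinstance(observed, JointFoldedSFS):
            observed = {tuple(observed.pops): observed}
        self.observed = dict(observed)
        self.factory = factory
        self.priors = dict(priors)
        self.samples = dict(samples)
        self.fixed_params = dict(fixed_params or {})
        self.model_id = model_id
        self.include_monomorphic = include_monomorphic
        self.pairs = list(self.observed)

    def expected(self, params: dict, n_sims: int, seed: int):
        model = self.factory({**self.fixed_params, **params})
        return expected_sfs(model, self.samples, pairs=self.pairs,
                            n_sims=n_sims, seed=seed,
                            polymorphic_only=not self.include_monomorphic)

    def loglike(self, params: dict, n_sims: int = 5000, seed: int = 1) -> float:
        try:
            exp = self.expected(params, n_sims=n_sims, seed=seed)
        except ValueError:
            return -math.inf
        return composite_log_likelihood(
            self.observed, exp, include_monomorphic=self.include_monomorphic)

    def polish(self, params: dict, n_sims: int = 25_000, seed: int = 1,
               maxiter: int = 150) -> "DemographyResults":
        """Local refinement by Nelder-Mead on a fixed genealogy stream.

        With a common random-number seed the Monte-Carlo composite
        likelihood is a deterministic function of the parameters, so a
        simplex search can climb correlated ridges that uniform random
        proposals traverse poorly.  Log-uniform parameters are optimised
        on the log scale; points outside the prior box score -inf.
        """
        from scipy.optimize import minimize

        names = list(self.priors)

        def to_x(p):
            out = []
            for k in names:
                v = float(p[k])
                out.append(np.log(v) if self.priors[k].dist == "loguniform"
                           else v)
            return np.array(out)

        def from_x(x):
            out = {}
            for k, v in zip(names, x):
                out[k] = float(np.exp(v)) if self.priors[k].dist == \
                    "loguniform" else float(v)
            return out

        def neg(x):
            p = from_x(x)
            for k in names:
                if not self.priors[k].low <= p[k] <= self.priors[k].high:
                    return 1e12
            return -self.loglike(p, n_sims=n_sims, seed=seed)

        x0 = to_x(params)
        res = minimize(neg, x0, method="Nelder-Mead",
                       options=dict(maxiter=maxiter, xatol=1e-3,
                                    fatol=0.05, adaptive=True))
        best = from_x(res.x) if -res.fun > self.loglike(
            params, n_sims=n_sims, seed=seed) else dict(params)
        lnl = self.loglike(best, n_sims=n_sims, seed=seed)
        gen_time = self.factory({**self.fixed_params, **best}).gen_time_years
        return DemographyResults(
            model_id=self.model_id,
            params=pd.Series({k: best[k] for k in names}, dtype=float),
            lnl=float(lnl),
            n_parameters=len(self.priors),
            trajectory=[(0, float(lnl))],
            seed=seed,
            gen_time_years=gen_time,
            n_sims=n_sims,
            model=self,
        )

    def fit(
        self,
        cycles: int = 40,
        proposals_per_cycle: int = 6,
        reinit_after: int = 3,
        range_shrink: float = 0.5,
        n_sims: int = 5000,
        n_runs: int = 1,
        seed: int = 0,
        init_values: dict | None = None,
    ) -> DemographyResults:
        """Cycle-based stochastic maximisation of the composite likelihood.

        Each cycle draws ``proposals_per_cycle`` parameter vectors from the
        current search ranges (initially the priors) and keeps the best
        point seen.  After ``reinit_after`` consecutive non-improving
        cycles the ranges are re-centred on the incumbent and shrunk by
        ``range_shrink``.  All evaluations within a run share one stream
        of simulated genealogies (common random numbers), so parameter
        vectors are compared on the same Monte-Carlo draw; independent
        runs (``n_runs``) vary that stream, and the best run wins.
        ``init_values`` seeds the incumbent (used by the parametric
        bootstrap to start refits at the point estimates).
        """
        root = np.random.SeedSequence(seed)
        best_overall = None
        for run, run_ss in enumerate(root.spawn(max(n_runs, 1))):
            rng = np.random.default_rng(run_ss)
            eval_seed = int(rng.integers(1, 2**31 - 1))
            bounds = {p: [pr.low, pr.high] for p, pr in self.priors.items()}
            trajectory = []

            def propose():
                return {p: self.priors[p].sample(rng, *bounds[p])
                        for p in self.priors}

            incumbent, inc_lnl = None, -math.inf
            first = []
            if init_values is not None:
                first.append({p: float(init_values[p]) for p in self.priors})
            first += [propose() for _ in range(proposals_per_cycle)]
            for cand in first:
                lnl = self.loglike(cand, n_sims=n_sims, seed=eval_seed)
                if lnl > inc_lnl:
                    incumbent, inc_lnl = cand, lnl
            trajectory.append((0, inc_lnl))
            strikes = 0
            for cycle in range(1, cycles + 1):
                improved = False
                for _ in range(proposals_per_cycle):
                    cand = propose()
                    lnl = self.loglike(cand, n_sims=n_sims, seed=eval_seed)
                    if lnl > inc_lnl:
                        incumbent, inc_lnl = cand, lnl
                        improved = True
                trajectory.append((cycle, inc_lnl))
                if improved:
                    strikes = 0
                    continue
                strikes += 1
                if strikes >= reinit_after and incumbent is not None:
                    for p in bounds:
                        pr = self.priors[p]
                        c = incumbent[p]
                        lo, hi = bounds[p]
                        if pr.dist == "loguniform":
                            half = 0.5 * range_shrink * (np.log(hi) - np.log(lo))
                            lo2 = max(np.log(pr.low), np.log(c) - half)
                            hi2 = min(np.log(pr.high), np.log(c) + half)
                            bounds[p] = [float(np.exp(lo2)), float(np.exp(hi2))]
                        else:
                            half = 0.5 * range_shrink * (hi - lo)
                            bounds[p] = [max(pr.low, c - half),
                                         min(pr.high, c + half)]
                    strikes = 0
            if incumbent is None:
                continue
            if best_overall is None or inc_lnl > best_overall[1]:
                best_overall = (incumbent, inc_lnl, trajectory, n_sims)
        if best_overall is None:
            raise RuntimeError(
                f"optimisation failed for {self.model_id}: no finite "
                "composite likelihood found in the prior ranges"
            )
        incumbent, inc_lnl, trajectory, used_sims = best_overall
        gen_time = self.factory({**self.fixed_params, **incumbent}).gen_time_years
        return DemographyResults(
            model_id=self.model_id,
            params=pd.Series(incumbent, dtype=float),
            lnl=float(inc_lnl),
            n_parameters=len(self.priors),
            trajectory=trajectory,
            seed=seed,
            gen_time_years=gen_time,
            n_sims=used_sims,
            model=self,
        )


def compare_models(models: list[SFSDemographyModel], seed: int = 0,
                   **fit_kw) -> tuple[pd.DataFrame, dict]:
    """Fit each candidate model and rank by AIC (ascending).

    Returns (table, results): the table carries lnL, the parameter count,
    AIC and delta-AIC; failed fits are recorded with NaN and excluded from
    the ranking.
    """
    if len(models) < 2:
        warnings.warn("comparing fewer than two models")
    rows, results = [], {}
    for k, m in enumerate(models):
        try:
            res = m.fit(seed=seed + 7919 * k, **fit_kw)
            results[m.model_id] = res
            rows.append(dict(model=m.model_id, lnl=res.lnl,
                             n_parameters=res.n_parameters, aic=res.aic))
        except Exception as exc:  # ranking proceeds over successes
            warnings.warn(f"model {m.model_id} failed: {exc}")
            rows.append(dict(model=m.model_id, lnl=np.nan,
                             n_parameters=np.nan, aic=np.nan))
    table = pd.DataFrame(rows).sort_values("aic", na_position="last")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table.reset_index(drop=True), results


def parametric_bootstrap(
    results: DemographyResults,
    n_datasets: int = 100,
    n_sites=None,
    seed: int = 0,
    sim_n_sims: int = 20_000,
    **fit_kw,
) -> pd.DataFrame:
    """Percentile confidence intervals via parametric bootstrap.

    Pseudo-observed spectra are simulated under the point estimates (site
    counts default to the observed per-pair totals), each is refitted with
    the optimiser initialised at the point values, and per-parameter 2.5 /
    50 / 97.5 percentiles of the refits are reported.  Fewer than 10
    successful refits flags the intervals unreliable.
    """
    model = results.model
    if model is None:
        raise ValueError("results are detached from their model")
    if n_sites is None:
        n_sites = {pair: int(round(_counts_of(o).sum()))
                   for pair, o in model.observed.items()}
    rng = np.random.default_rng(seed)
    point = dict(results.params)
    fit_kw.setdefault("cycles", 10)
    fit_kw.setdefault("n_sims", max(results.n_sims, 1000))
    draws = []
    for b in range(n_datasets):
        sim = simulate_sfs_counts(
            model.factory({**model.fixed_params, **point}),
            model.samples, n_sites, pairs=model.pairs,
            seed=int(rng.integers(1, 2**31 - 1)), n_sims=sim_n_sims,
            polymorphic_only=not model.include_monomorphic,
        )
        boot = SFSDemographyModel(sim, model.factory, model.priors,
                                  model.samples, model.fixed_params,
                                  model_id=f"{model.model_id}_boot{b}",
                                  include_monomorphic=model.include_monomorphic)
        try:
            res = boot.fit(seed=int(rng.integers(1, 2**31 - 1)),
                           init_values=point, **fit_kw)
            draws.append(res.params)
        except RuntimeError:
            continue
    if not draws:
        raise RuntimeError("no successful bootstrap refits")
    D = pd.DataFrame(draws)
    out = pd.DataFrame({
        "point": pd.Series(point),
        "ci_low": D.quantile(0.025),
        "median": D.quantile(0.5),
        "ci_high": D.quantile(0.975),
    })
    out.attrs["n_success"] = len(D)
    out.attrs["reliable"] = len(D) >= 10
    return out


# ---------------------------------------------------------------------------
# Preset factories and priors
# ---------------------------------------------------------------------------

def pair_model_factory(bottleneck: bool = True,
                       pop_names: tuple[str, str] = ("cultivated", "wild")):
    """Factory for the cultivated/wild pair model.

    Free/fixed parameters: N_CULT, N_WILD, N_ANC, T_DIV and, with a
    bottleneck, N_BOT and T_EXP (expansion time).  Sizes are diploid;
    times are generations before present.
    """

    def build(params: dict) -> DemographicModel:
        return two_population_model(
            n_cultivated=params["N_CULT"],
            n_wild=params["N_WILD"],
            n_ancestral=params["N_ANC"],
            t_div=params["T_DIV"],
            bottleneck_size=params["N_BOT"] if bottleneck else None,
            t_expansion=params.get("T_EXP", 2000.0) if bottleneck else 2000.0,
            pop_names=pop_names,
        )

    return build


PAIR_PRIORS_DEFAULT: dict[str, Prior] = {
    "N_CULT": Prior("loguniform", 100, 200_000),
    "N_WILD": Prior("loguniform", 100, 200_000),
    "N_ANC": Prior("loguniform", 100, 200_000),
    "N_BOT": Prior("loguniform", 10, 50_000),
    "T_DIV": Prior("uniform", 100, 100_000),
    "T_EXP": Prior("uniform", 10, 20_000),
}
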