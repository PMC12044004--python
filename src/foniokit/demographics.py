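"""Demographic models: populations, splits, size changes and bottlenecks.

Time is measured in generations before present; population sizes are
diploid effective sizes N; coalescence within a population of size N
happens at rate k(k-1)/2 per 2N generations.  A *split* is expressed
backward in time: at time ``t`` the lineages of the derived population
move into the ancestral one.  A *bottleneck* is a size reduction over the
interval ``[t_start, t_end]`` (t_start more recent than t_end).

Defaults mirror a two-crop domestication system: an annual selfing grass
with mutation rate 6.5e-9 per bp per generation and a one-year generation
time; each cultivated lineage passes through a post-divergence bottleneck
followed by a recent expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU_DEFAULT = 6.5e-9

# kernel event codes
EV_JOIN = 0
EV_SIZE = 1

__all__ = [
    "MU_DEFAULT",
    "Split",
    "SizeChange",
    "Bottleneck",
    "DemographicModel",
    "two_population_model",
    "four_population_model",
]


class ModelError(ValueError):
    """Structurally invalid demographic model."""


@dataclass(frozen=True)
class Split:
    """Backward in time at ``time``, ``derived`` merges into ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class SizeChange:
    """At ``time`` (going backward), ``pop`` takes diploid size ``size``."""

    time: float
    pop: str
    size: float


@dataclass(frozen=True)
class Bottleneck:
    """``pop`` has reduced diploid size ``size`` on ``[t_start, t_end]``."""

    t_start: float
    t_end: float
    pop: str
    size: float


@dataclass
class DemographicModel:
    pop_names: list[str]
    pop_sizes: dict[str, float]
    events: list = field(default_factory=list)
    mu: float = MU_DEFAULT
    gen_time_years: float = 1.0
    selfing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ModelError("mutation rate must be positive")
        for p in self.pop_names:
            if p not in self.pop_sizes:
                raise ModelError(f"no size for population {p!r}")
        for p, n in self.pop_sizes.items():
            if n <= 0:
                raise ModelError(f"population size must be positive ({p}={n})")
        if not 0.0 <= self.selfing_rate < 1.0:
            raise ModelError("selfing_rate must be in [0, 1)")
        for ev in self.events:
            t0 = ev.t_start if isinstance(ev, Bottleneck) else ev.time
            if t0 < 0:
                raise ModelError("event times must be >= 0")
            if isinstance(ev, Bottleneck) and ev.t_end <= ev.t_start:
                raise ModelError("bottleneck requires t_end > t_start")
        self._check_tree()

    def _check_tree(self) -> None:
        """Every population must merge into the tree exactly once."""
        merged: dict[str, float] = {}
        for ev in self.events:
            if isinstance(ev, Split):
                if ev.derived in merged:
                    raise ModelError(f"{ev.derived!r} merges more than once")
                if ev.derived not in self.pop_sizes or ev.ancestral not in self.pop_sizes:
                    raise ModelError("split references unknown population")
                merged[ev.derived] = ev.time
        roots = [p for p in self.pop_sizes if p not in merged]
        if len(self.pop_names) > 1 and len(roots) != 1:
            raise ModelError(
                f"populations must coalesce into a single root, found roots {roots}"
            )
        # follow each sampled pop up the tree; detect cycles / dead lineages
        splits = {ev.derived: ev for ev in self.events if isinstance(ev, Split)}
        for p in self.pop_names:
            seen = set()
            cur, t = p, 0.0
            while cur in splits:
                if cur in seen:
                    raise ModelError("cycle in split events")
                seen.add(cur)
                ev = splits[cur]
                if ev.time < t:
                    raise ModelError("splits not topologically ordered in time")
                cur, t = ev.ancestral, ev.time

    # ------------------------------------------------------------------
    def selfing_adjusted_sizes(self) -> dict[str, float]:
        """Diploid sizes rescaled by 1/(1+F) with F = s/(2-s).

        Partial self-fertilisation reduces the effective number of
        independent lineages; rescaling N is the classical first-order
        approximation (no explicit selfing genealogies are simulated).
        """
        s = self.selfing_rate
        f = s / (2.0 - s)
        return {p: n / (1.0 + f) for p, n in self.pop_sizes.items()}

    def compile_events(self):
        """Flatten the event list into sorted kernel arrays.

        Returns (pop_index, sizes0, ev_time, ev_kind, ev_a, ev_b) where
        pop_index maps population name -> integer slot.
        """
        pops = list(self.pop_sizes)
        idx = {p: i for i, p in enumerate(pops)}
        sizes = self.selfing_adjusted_sizes()
        scale = sizes[pops[0]] / self.pop_sizes[pops[0]] if pops else 1.0

        # entries: [t, kind, a, b, sort_priority, tag]; tag "base" marks
        # explicit size changes, "restore" marks bottleneck-end placeholders
        prim: list[list] = []
        for ev in self.events:
            if isinstance(ev, Split):
                prim.append([ev.time, EV_JOIN, idx[ev.derived], float(idx[ev.ancestral]), 1, ""])
            elif isinstance(ev, SizeChange):
                prim.append([ev.time, EV_SIZE, idx[ev.pop], ev.size * scale, 0, "base"])
            elif isinstance(ev, Bottleneck):
                prim.append([ev.t_start, EV_SIZE, idx[ev.pop], ev.size * scale, 0, ""])
                prim.append([ev.t_end, EV_SIZE, idx[ev.pop], None, 2, "restore"])
            else:  # pragma: no cover
                raise ModelError(f"unknown event type {type(ev)}")
        # size changes apply before joins at the same instant; restores last
        prim.sort(key=lambda e: (e[0], e[4]))
        # a bottleneck-end restores the size the population would have had
        # without the bottleneck: the most recent explicit size change at or
        # below that time, else the present-day size
        resolved = prim
        for entry in resolved:
            if entry[5] != "restore":
                continue
            t, a = entry[0], entry[2]
            restore = sizes[pops[a]]
            for t2, kind2, a2, b2, _pri, tag2 in resolved:
                if tag2 == "base" and a2 == a and t2 <= t:
                    restore = b2
            entry[3] = restore
        ev_time = np.array([e[0] for e in resolved], dtype=np.float64)
        ev_kind = np.array([e[1] for e in resolved], dtype=np.int64)
        ev_a = np.array([e[2] for e in resolved], dtype=np.int64)
        ev_b = np.array([e[3] for e in resolved], dtype=np.float64)
        sizes0 = np.array([sizes[p] for p in pops], dtype=np.float64)
        return idx, sizes0, ev_time, ev_kind, ev_a, ev_b


# ---------------------------------------------------------------------------
# Preset model builders
# ---------------------------------------------------------------------------

def two_population_model(
    *,
    n_cultivated: float = 10_000.0,
    n_wild: float = 20_000.0,
    n_ancestral: float = 20_000.0,
    t_div: float = 25_000.0,
    bottleneck_size: float | None = 2_000.0,
    t_expansion: float = 2_000.0,
    mu: float = MU_DEFAULT,
    pop_names: tuple[str, str] = ("cultivated", "wild"),
) -> DemographicModel:
    """Cultivated/wild pair: divergence at ``t_div`` with an optional
    post-divergence bottleneck in the cultivated lineage followed by an
    expansion ``t_expansion`` generations ago.

    Backward in time the cultivated population has its present size until
    ``t_expansion``, the bottleneck size from there until the divergence,
    and the pair's ancestor has size ``n_ancestral``.
    """
    cult, wild = pop_names
    events: list = []
    if bottleneck_size is not None:
        if not 0 < t_expansion < t_div:
            raise ModelError("need 0 < t_expansion < t_div for a bottleneck")
        events.append(Bottleneck(t_expansion, t_div, cult, bottleneck_size))
    events.append(Split(t_div, cult, wild))
    events.append(SizeChange(t_div, wild, n_ancestral))
    return DemographicModel(
        pop_names=[cult, wild],
        pop_sizes={cult: n_cultivated, wild: n_wild},
        events=events,
        mu=mu,
    )


def four_population_model(
    *,
    pop_names: tuple[str, str, str, str] = ("exilis", "longiflora", "iburua", "ternata"),
    sizes: dict[str, float] | None = None,
    t_pair1: float = 25_000.0,
    t_pair2: float = 10_000.0,
    t_deep: float = 300_000.0,
    n_ancestral: float = 20_000.0,
    bottlenecks: bool = True,
    bottleneck_size: float = 2_000.0,
    t_expansion: float = 2_000.0,
    mu: float = MU_DEFAULT,
) -> DemographicModel:
    """Two cultivated/wild pairs with a deep between-pair divergence.

    ``pop_names`` is (cultivated1, wild1, cultivated2, wild2); cultivated1
    splits from wild1 at ``t_pair1``, cultivated2 from wild2 at ``t_pair2``,
    and the two wild lineages join at ``t_deep``.  With ``bottlenecks`` each
    cultivated lineage carries a post-divergence bottleneck and a recent
    expansion.  There is no migration: the pairs diverge without gene flow.
    """
    c1, w1, c2, w2 = pop_names
    if sizes is None:
        sizes = {c1: 10_000.0, w1: 20_000.0, c2: 10_000.0, w2: 20_000.0}
    events: list = []
    if bottlenecks:
        events.append(Bottleneck(t_expansion, t_pair1, c1, bottleneck_size))
        events.append(Bottleneck(t_expansion, t_pair2, c2, bottleneck_size))
    events += [
        Split(t_pair1, c1, w1),
        SizeChange(t_pair1, w1, n_ancestral),
        Split(t_pair2, c2, w2),
        SizeChange(t_pair2, w2, n_ancestral),
        Split(t_deep, w2, w1),
        SizeChange(t_deep, w1, n_ancestral),
    ]
    if not (t_pair1 < t_deep and t_pair2 < t_deep):
        raise ModelError("between-pair split must be older than within-pair splits")
    return DemographicModel(
        pop_names=list(pop_names),
        pop_sizes=dict(sizes),
        events=events,
        mu=mu,
    )
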