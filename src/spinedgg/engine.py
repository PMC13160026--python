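"""Generic rule machinery: continuous-time exact stochastic simulation
over graph-rewrite rule instances.

A :class:`Rule` knows how to enumerate its concrete embeddings
(:class:`RuleInstance`) in a :class:`SimState` together with their
propensities (the "with" clause), and how to apply its rewrite effect.
The scheduler is the Gillespie direct method: waiting times are
exponential in the total propensity and one instance fires per event,
chosen with probability proportional to its propensity.  All rules --
biochemical remodeling, mechanical kinetics, thermal noise, membrane
relaxation -- compete on the single shared clock; the pool ODEs are
advanced deterministically over each waiting time (hybrid ODE/SSA).

Instances are re-enumerated freshly each step, and :func:`fire`
validates an instance's node ids against the live graph, so a stale
embedding (from a cached instance list) is rejected without touching
the state.
"""

from __future__ import annotations

import abc
import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .graph import LabeledGraph
from .membrane import Attachment, MembranePolygon
from .params import Params
from .pools import SpeciesPools


class QuiescentState(Exception):
    """Total propensity is zero; no stochastic event can fire."""


class StaleInstanceError(Exception):
    """The instance refers to ids no longer present in the state."""


@dataclasses.dataclass
class RuleInstance:
    rule: "Rule"
    key: tuple
    propensity: float

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.rule.name}{self.key} a={self.propensity:.3g}>"


GROUP_KEY = ("__group__",)


class Rule(abc.ABC):
    """A local LHS motif + propensity clause + rewrite effect.

    Rules whose embeddings all share one propensity (the k_kinetic
    mechanical rules) may set ``uniform_group = True`` and provide
    ``members``/``member_propensity``: the scheduler then carries one
    aggregate instance of propensity k * n and draws the concrete
    embedding uniformly at fire time -- statistically identical to
    enumerating every embedding, without materializing thousands of
    equal instances per event.  ``instances`` still enumerates every
    embedding for pattern-matching queries and tests.
    """

    name: str = "rule"
    uniform_group: bool = False

    @abc.abstractmethod
    def instances(self, state: "SimState") -> list[RuleInstance]:
        """Every embedding of the LHS motif with nonzero propensity."""

    @abc.abstractmethod
    def execute(self, state: "SimState", instance: RuleInstance) -> None:
        """Apply the rewrite; samplers draw from ``state.rng``."""

    def is_valid(self, state: "SimState", instance: RuleInstance) -> bool:
        """Default validity: every integer id in the key is a live node."""
        return all(k in state.graph.nodes
                   for k in instance.key if isinstance(k, int))

    # -- uniform-group fast path --------------------------------------
    def members(self, state: "SimState") -> Sequence[tuple]:
        raise NotImplementedError

    def member_propensity(self, state: "SimState") -> float:
        raise NotImplementedError


@dataclasses.dataclass
class SimState:
    """The single mutable object all rules rewrite."""

    params: Params
    graph: LabeledGraph
    membrane: MembranePolygon
    pools: SpeciesPools
    attachments: dict[int, Attachment] = dataclasses.field(default_factory=dict)
    time: float = 0.0
    rng: np.random.Generator = dataclasses.field(
        default_factory=lambda: np.random.default_rng(0))
    rules: list[Rule] = dataclasses.field(default_factory=list)
    maintenance: list[Callable[["SimState"], None]] = dataclasses.field(
        default_factory=list)
    event_log: Optional[list[tuple[float, str, tuple]]] = None
    _next_attachment_id: int = 0
    #: scratch cache, valid only while one step's instances are enumerated
    cache: dict = dataclasses.field(default_factory=dict)

    @property
    def area(self) -> float:
        if "area" not in self.cache:
            self.cache["area"] = self.membrane.signed_area()
        return self.cache["area"]

    def register(self, *rules: Rule) -> None:
        self.rules.extend(rules)

    def new_attachment(self, end_id: int, vertex_id: int,
                       rest_length: float) -> Attachment:
        att = Attachment(self._next_attachment_id, end_id, vertex_id,
                         rest_length, self.time)
        self._next_attachment_id += 1
        self.attachments[att.id] = att
        return att

    def attachment_for_end(self, end_id: int) -> Optional[Attachment]:
        for att in self.attachments.values():
            if att.end_id == end_id:
                return att
        return None


def enumerate_instances(state: SimState, rule: Rule) -> list[RuleInstance]:
    """All embeddings of ``rule`` in ``state`` with their propensities."""
    out = rule.instances(state)
    if out:
        a = np.fromiter((inst.propensity for inst in out), dtype=float,
                        count=len(out))
        if np.any(a < 0.0) or not np.all(np.isfinite(a)):
            bad = out[int(np.argmin(np.isfinite(a) & (a >= 0)))]
            raise ValueError(
                f"rule {rule.name} produced invalid propensity "
                f"{bad.propensity!r} for key {bad.key}")
    return out


def cached(state: SimState, key: str, builder: Callable[[], object]):
    """Memoize a per-step derived quantity (adjacency, triples, ...).

    The cache is cleared before each step's enumeration and must not be
    consulted by rule effects, which see the mutated state.
    """
    if key not in state.cache:
        state.cache[key] = builder()
    return state.cache[key]


def all_instances(state: SimState) -> list[RuleInstance]:
    state.cache.clear()
    out: list[RuleInstance] = []
    for rule in state.rules:
        if rule.uniform_group:
            n = len(rule.members(state))
            if n:
                out.append(RuleInstance(
                    rule, GROUP_KEY, n * rule.member_propensity(state)))
        else:
            out.extend(enumerate_instances(state, rule))
    return out


def fire(state: SimState, instance: RuleInstance) -> None:
    """Apply one instance atomically; stale embeddings are rejected."""
    if instance.key is GROUP_KEY or instance.key == GROUP_KEY:
        members = instance.rule.members(state)
        if not members:
            raise StaleInstanceError(
                f"group instance of {instance.rule.name} has no members")
        key = members[int(state.rng.integers(len(members)))]
        instance = RuleInstance(instance.rule, key,
                                instance.rule.member_propensity(state))
    if not instance.rule.is_valid(state, instance):
        raise StaleInstanceError(
            f"stale instance of {instance.rule.name}: {instance.key}")
    instance.rule.execute(state, instance)
    if state.event_log is not None:
        state.event_log.append((state.time, instance.rule.name, instance.key))


def step(state: SimState) -> tuple[RuleInstance, float]:
    """One exact-SSA event: sample dt ~ Exp(a0), pick an instance with
    probability proportional to its propensity, fire it, advance the
    pool ODEs over dt, run maintenance hooks, advance the clock."""
    instances = all_instances(state)
    if not instances:
        raise QuiescentState(f"total propensity is zero at t={state.time}")
    cum = np.cumsum(np.fromiter((inst.propensity for inst in instances),
                                dtype=float, count=len(instances)))
    a0 = float(cum[-1])
    if a0 <= 0.0:
        raise QuiescentState(f"total propensity is zero at t={state.time}")
    dt = float(state.rng.exponential(1.0 / a0))
    u = state.rng.uniform(0.0, a0)
    chosen = instances[min(int(np.searchsorted(cum, u)), len(instances) - 1)]
    area_before = state.area
    fire(state, chosen)
    state.cache.clear()
    state.pools.ode_advance(dt, area_before)
    state.time += dt
    for hook in state.maintenance:
        hook(state)
    return chosen, dt


def run(state: SimState, t_end: float,
        snapshot_every: Optional[float] = None,
        on_snapshot: Optional[Callable[[SimState], None]] = None,
        max_events: Optional[int] = None) -> int:
    """Advance the state to ``t_end``; returns the number of events fired.

    On quiescence the pools are advanced deterministically to ``t_end``.
    """
    n_events = 0
    next_snap = state.time + snapshot_every if snapshot_every else None
    while state.time < t_end:
        if max_events is not None and n_events >= max_events:
            break
        try:
            step(state)
        except QuiescentState:
            state.pools.ode_advance(t_end - state.time, state.area)
            state.time = t_end
            break
        n_events += 1
        if next_snap is not None and state.time >= next_snap:
            if on_snapshot is not None:
                on_snapshot(state)
            next_snap += snapshot_every
    return n_events
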