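"""Programmatic construction of simulation states and small test
fixtures.  Everything is generated from code and a seed; there are no
data files.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .engine import SimState
from .graph import ActinNode, LabeledGraph
from .kinetics import kinetic_rules
from .membrane import MembranePolygon, make_circle, make_ellipse
from .params import Params, default_params
from .pools import init_steady_state
from .remodeling import (attach_intersecting_ends, detach_far_ends,
                         remodeling_rules)


def _atp_node(g: LabeledGraph, x, n_cg: int, **kw) -> ActinNode:
    return g.add_node(ActinNode(g.new_id(), np.asarray(x, dtype=float),
                                n_atp=n_cg, **kw))


def build_state(params: Params, graph: LabeledGraph,
                membrane: MembranePolygon, seed: int,
                stimulated: bool = False,
                with_rules: bool = True) -> SimState:
    pools = init_steady_state(params, membrane.signed_area(),
                              stimulated=stimulated)
    state = SimState(params=params, graph=graph, membrane=membrane,
                     pools=pools, rng=np.random.default_rng(seed))
    if with_rules:
        state.register(*remodeling_rules(), *kinetic_rules())
        state.maintenance.extend([attach_intersecting_ends, detach_far_ends])
    return state


def seed_spine(params: Optional[Params] = None, seed: int = 0,
               stimulated: bool = False, with_rules: bool = True) -> SimState:
    """The standard initial condition: a circular membrane of the
    starting spine-head radius enclosing a two-object seed filament at
    the center, pools at their basal steady state."""
    params = params or default_params()
    membrane = make_circle(params.r_spine_int,
                           int(params.raw["n_membrane_vertices"]))
    g = LabeledGraph()
    a = _atp_node(g, (-0.5, 0.0), params.n_cg)
    b = _atp_node(g, (0.5, 0.0), params.n_cg)
    g.set_next(a.id, b.id)
    return build_state(params, g, membrane, seed, stimulated=stimulated,
                       with_rules=with_rules)


def straight_filament(n: int, params: Optional[Params] = None, seed: int = 0,
                      with_rules: bool = False, all_adp: bool = False,
                      spacing: float = 1.0) -> SimState:
    """An unbranched n-object filament along +x inside a roomy membrane."""
    params = params or default_params()
    g = LabeledGraph()
    prev = None
    for i in range(n):
        kw = {"n_adp": params.n_cg} if all_adp else {"n_atp": params.n_cg}
        node = g.add_node(ActinNode(g.new_id(),
                                    np.array([i * spacing, 0.0]), **kw))
        if prev is not None:
            g.set_next(prev.id, node.id)
        prev = node
    radius = max(params.r_spine_int, n * spacing + 2.0)
    membrane = make_circle(radius, int(params.raw["n_membrane_vertices"]),
                           center=((n - 1) * spacing / 2.0, 0.0))
    return build_state(params, g, membrane, seed, with_rules=with_rules)


def branched_y(params: Optional[Params] = None, seed: int = 0,
               with_rules: bool = False) -> SimState:
    """Three-object parent with a one-object daughter at ~70 degrees."""
    params = params or default_params()
    state = straight_filament(3, params, seed, with_rules=with_rules)
    g = state.graph
    mid = sorted(g.nodes)[1]
    theta = params.raw["theta_arp"]
    direction = np.array([math.cos(theta), math.sin(theta)])
    node = g.add_node(ActinNode(g.new_id(), g.nodes[mid].x + direction,
                                n_atp=params.n_cg))
    g.set_daughter(mid, node.id)
    g.refresh_angles()
    return state


def bundled_pair(params: Optional[Params] = None, seed: int = 0,
                 separation: float = 0.5,
                 with_rules: bool = False) -> SimState:
    """Two parallel three-object filaments joined by a CaMKII-beta link
    between their middle objects."""
    params = params or default_params()
    state = straight_filament(3, params, seed, with_rules=with_rules)
    g = state.graph
    prev = None
    for i in range(3):
        node = g.add_node(ActinNode(g.new_id(),
                                    np.array([float(i), separation]),
                                    n_atp=params.n_cg))
        if prev is not None:
            g.set_next(prev.id, node.id)
        prev = node
    g.add_link(1, 4, rest_length=separation)
    return state


def cofilactin_boundary_filament(params: Optional[Params] = None,
                                 seed: int = 0, n: int = 6,
                                 with_rules: bool = False) -> SimState:
    """Straight ADP filament whose barbed half is cofilin-decorated,
    creating a cofilactin-actin boundary in the middle."""
    params = params or default_params()
    state = straight_filament(n, params, seed, with_rules=with_rules,
                              all_adp=True)
    for nid in sorted(state.graph.nodes)[n // 2:]:
        node = state.graph.nodes[nid]
        node.n_cof = node.n_mono
    return state


def ellipse_membrane(a: float, b: float, params: Optional[Params] = None,
                     seed: int = 0, n_vertices: Optional[int] = None,
                     with_rules: bool = False) -> SimState:
    """A bare elliptical membrane with no cytoskeleton."""
    params = params or default_params()
    nv = n_vertices or int(params.raw["n_membrane_vertices"])
    return build_state(params, LabeledGraph(), make_ellipse(a, b, nv),
                       seed, with_rules=with_rules)


_FIXTURES = {
    "seed_spine": seed_spine,
    "straight_filament": lambda params, seed: straight_filament(5, params, seed),
    "branched_Y": branched_y,
    "bundled_pair": bundled_pair,
    "cofilactin_boundary_filament": cofilactin_boundary_filament,
    "ellipse_membrane": lambda params, seed: ellipse_membrane(4.0, 2.0,
                                                              params, seed),
}


def make_fixture(name: str, seed: int = 0,
                 params: Optional[Params] = None) -> SimState:
    """Named deterministic fixtures used throughout the test surface."""
    try:
        ctor = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {sorted(_FIXTURES)}") from None
    return ctor(params or default_params(), seed)
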