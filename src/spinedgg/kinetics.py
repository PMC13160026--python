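"""Mechanical DGG rules: anisotropic buckling (interior / branch / end
motifs), angle bending, Hessian thermal noise, and membrane vertex
relaxation.

Every rule fires at the generic kinetics propensity ``k_kinetic`` per
instance and applies a single overdamped update

    dx = -(1 / (zeta * k_kinetic)) * grad U

to its central node; in the limit ``k_kinetic -> infinity`` this is a
stochastic forward-Euler solver of the force-balance ODE dx/dt =
-grad U / zeta.  Thermal noise is a Metropolis-Hastings heat bath whose
Gaussian proposal has covariance ``s * kT * H^-1`` built from the local
buckling Hessian, accepted with the Barker (heat-bath) probability
A = t/(1+t), t the exact detailed-balance ratio including the Gaussian
normalization (determinant) factors.

The three buckling motifs are mutually exclusive: a node with exactly
one filament-graph neighbor is an end, two an interior node, three a
branch point.  Bundle links and membrane attachments contribute extra
separation-potential edges to the gradients and Hessians but do not
change the motif.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .engine import Rule, RuleInstance, SimState
from .mechanics import (Bond, Edge, angle_gradient_end,
                        angle_gradient_interior, radial_gradient)
from .membrane import helfrich_gradient


def bond_between(state: SimState, parent: int, child: int) -> Bond:
    """Filament bond; its rest length is carried by the downstream node."""
    return Bond(state.params.eps_lj_int,
                state.graph.nodes[child].rest_length,
                state.params.raw["eps_clip"])


def separation_edges(state: SimState, nid: int) -> list[Edge]:
    """All separation-potential edges at a node: filament neighbors,
    bundle link partner, and membrane attachment."""
    g = state.graph
    node = g.nodes[nid]
    p = state.params
    edges: list[Edge] = []
    for child in (node.next_id, node.daughter_id):
        if child is not None:
            edges.append(Edge(g.nodes[child].x, bond_between(state, nid, child)))
    for parent in g.prev_ids(nid):
        edges.append(Edge(g.nodes[parent].x, bond_between(state, parent, nid)))
    if node.camkii_link is not None:
        link = g.links[node.camkii_link]
        other = link.node_b if link.node_a == nid else link.node_a
        edges.append(Edge(g.nodes[other].x,
                          Bond(p.eps_lj_int, link.rest_length,
                               p.raw["eps_clip"])))
    att = state.attachment_for_end(nid)
    if att is not None and att.vertex_id in state.membrane.pos:
        edges.append(Edge(state.membrane.pos[att.vertex_id],
                          Bond(p.eps_lj_int, att.rest_length,
                               p.raw["eps_clip"])))
    return edges


def degree_map(state: SimState) -> dict[int, int]:
    from .engine import cached
    return cached(state, "degree_map",
                  lambda: {nid: len(state.graph.neighbors(nid))
                           for nid in state.graph.nodes})


def filament_degree(state: SimState, nid: int) -> int:
    return len(state.graph.neighbors(nid))


def mech_members(state: SimState) -> dict:
    """One pass over the graph collecting the member lists of every
    uniform-propensity mechanical rule (buckling motifs by degree,
    bending triples, all nodes)."""
    from .engine import cached

    def build() -> dict:
        g = state.graph
        by_degree: dict[int, list[tuple]] = {1: [], 2: [], 3: []}
        triples: list[tuple] = []
        nodes: list[tuple] = []
        for nid in sorted(g.nodes):
            node = g.nodes[nid]
            nodes.append((nid,))
            preds = g.prev_ids(nid)
            succs = [t for t in (node.next_id, node.daughter_id)
                     if t is not None]
            deg = len(preds) + len(succs)
            if deg in by_degree:
                by_degree[deg].append((nid,))
            for i in preds:
                for k in succs:
                    triples.append((i, nid, k))
        return {"deg": by_degree, "triples": triples, "nodes": nodes}

    return cached(state, "mech_members", build)


def _try_move(state: SimState, nid: int, new_x: np.ndarray) -> bool:
    """Move an actin node if it stays inside the membrane (within the
    overgrowth tolerance); returns whether the move was applied."""
    tol = state.params.raw["overgrowth_length"]
    if not state.membrane.contains(new_x, tolerance=tol):
        return False
    state.graph.nodes[nid].x = np.asarray(new_x, dtype=float)
    state.graph.refresh_angles_around(nid)
    return True


class _BucklingBase(Rule):
    degree: int = 0
    uniform_group = True

    def members(self, state: SimState):
        return mech_members(state)["deg"][self.degree]

    def member_propensity(self, state: SimState) -> float:
        return state.params.raw["k_kinetic"]

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_kinetic"]
        return [RuleInstance(self, key, k) for key in self.members(state)]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid = inst.key[0]
        p = state.params
        node = state.graph.nodes[nid]
        grad = radial_gradient(node.x, separation_edges(state, nid))
        delta = -grad / (p.zeta_actin_int * p.raw["k_kinetic"])
        _try_move(state, nid, node.x + delta)


class BucklingEnd(_BucklingBase):
    """End-case anisotropic buckling: one filament neighbor."""

    name = "buckling_end"
    degree = 1


class BucklingInterior(_BucklingBase):
    """Interior-case anisotropic buckling: the trinodal gradient, whose
    exact vector sum cancels longitudinal components on a straight run."""

    name = "buckling_interior"
    degree = 2


class BucklingBranch(_BucklingBase):
    """Branch-case anisotropic buckling at a junction (quad-nodal)."""

    name = "buckling_branch"
    degree = 3


def effective_k_bend(state: SimState, nid: int) -> float:
    """Bending stiffness softened up to 5x by bound cofilin (linear in
    the cofilin fraction of the bending node)."""
    p = state.params
    frac = state.graph.nodes[nid].cof_fraction
    soften = 1.0 + (p.raw["cofilin_soften"] - 1.0) * frac
    return p.k_bend_int / soften


def triple_target(state: SimState, i: int, j: int, k: int) -> float:
    """Preferred angle for the typed triple: +-70 degrees across a branch
    (signed by the current geometry), zero along a straight run."""
    node_j = state.graph.nodes[j]
    if node_j.daughter_id is not None and k == node_j.daughter_id:
        sign = 1.0 if node_j.theta_branch >= 0 else -1.0
        return sign * state.params.raw["theta_arp"]
    return 0.0


class _BendBase(Rule):
    move: str = "center"   # which node of the triple is updated
    uniform_group = True

    def members(self, state: SimState):
        return mech_members(state)["triples"]

    def member_propensity(self, state: SimState) -> float:
        return state.params.raw["k_kinetic"]

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_kinetic"]
        return [RuleInstance(self, t, k) for t in self.members(state)]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        i, j, k = inst.key
        g = state.graph
        p = state.params
        x1, x2, x3 = g.nodes[i].x, g.nodes[j].x, g.nodes[k].x
        kb = effective_k_bend(state, j)
        target = triple_target(state, i, j, k)
        if self.move == "center":
            grad = angle_gradient_interior(x1, x2, x3, target, kb)
            nid, x = j, x2
        elif self.move == "first":
            grad = angle_gradient_end(x1, x2, x3, target, kb, which="first")
            nid, x = i, x1
        else:
            grad = angle_gradient_end(x1, x2, x3, target, kb, which="last")
            nid, x = k, x3
        delta = -grad / (p.zeta_actin_int * p.raw["k_kinetic"])
        _try_move(state, nid, x + delta)


class AngleBendingCenter(_BendBase):
    """Angle bending rule 1: the middle node of the triple moves."""

    name = "angle_bending_center"
    move = "center"


class AngleBendingFirst(_BendBase):
    name = "angle_bending_first"
    move = "first"


class AngleBendingLast(_BendBase):
    name = "angle_bending_last"
    move = "last"


# ---------------------------------------------------------------------
# thermal noise
# ---------------------------------------------------------------------

def proposal_precision(state: SimState, nid: int,
                       x: Optional[np.ndarray] = None) -> float:
    """Isotropic precision scale h of the thermal proposal at a node:
    sum of |U''| over the local separation edges plus the regularizer.

    Using |U''| keeps h positive on the anharmonic tail (where U'' < 0);
    at rest separation it equals the buckling graph-Laplacian diagonal,
    and the Barker acceptance makes any positive h exactly
    detailed-balanced.
    """
    if x is None:
        x = state.graph.nodes[nid].x
    edges = separation_edges(state, nid)
    h = sum(abs(e.bond.d2u(float(np.linalg.norm(x - e.xj)))) for e in edges)
    return h + state.params.raw["eps_sep"] ** 2


def local_sep_energy(state: SimState, nid: int, x: np.ndarray) -> float:
    return sum(e.bond.u(float(np.linalg.norm(x - e.xj)))
               for e in separation_edges(state, nid))


def thermal_acceptance(du: float, h_old: float, h_new: float,
                       u2: float, scale: float) -> float:
    """Heat-bath (Barker) acceptance A = t/(1+t) with

    ln t = -dU + (d/2) ln(h'/h) - |u|^2 (h' - h) / (2 s),

    the exact detailed-balance ratio for target exp(-U/kT) and the
    Gaussian proposal N(0, s*kT/h * I) in d = 2 dimensions; dU and the
    proposal (Hessian) energies enter in units of kT.
    """
    ln_t = -du + math.log(h_new / h_old) - u2 * (h_new - h_old) / (2.0 * scale)
    if ln_t > 500.0:
        return 1.0
    t = math.exp(ln_t)
    return t / (1.0 + t)


class ThermalNoise(Rule):
    """Hessian Boltzmann sampling of a single node (interior and end
    cases share the implementation; only the edge set differs)."""

    name = "thermal_noise"
    uniform_group = True

    def members(self, state: SimState):
        return mech_members(state)["nodes"]

    def member_propensity(self, state: SimState) -> float:
        return state.params.raw["k_kinetic"]

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_kinetic"]
        return [RuleInstance(self, key, k) for key in self.members(state)]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid = inst.key[0]
        node = state.graph.nodes[nid]
        scale = state.params.raw["thermal_step_scale"]
        h_old = proposal_precision(state, nid)
        u = state.rng.normal(0.0, math.sqrt(scale / h_old), size=2)
        x_new = node.x + u
        h_new = proposal_precision(state, nid, x_new)
        du = (local_sep_energy(state, nid, x_new)
              - local_sep_energy(state, nid, node.x))
        a = thermal_acceptance(du, h_old, h_new, float(np.dot(u, u)), scale)
        if state.rng.uniform() < a:
            _try_move(state, nid, x_new)


def single_pair_thermal_chain(bond: Bond, n_steps: int,
                              rng: np.random.Generator,
                              scale: float = 1.0,
                              eps_sep: float = 1e-6) -> np.ndarray:
    """Run the heat-bath thermal chain for one mobile node bonded to a
    fixed partner at the origin; returns the sampled separations.

    This is the two-object reduction of the thermal-noise rule: Gaussian
    proposals with precision |U''(r)|/(s kT) and Barker acceptance
    targeting exp(-U(r)/kT).  In the harmonic regime the stationary
    separation variance is kT/U''(r_min) (equipartition).
    """
    x0, x1 = bond.rest_length, 0.0
    out = np.empty(n_steps)
    eps2 = eps_sep ** 2
    for i in range(n_steps):
        r = math.hypot(x0, x1)
        h = abs(bond.d2u(r)) + eps2
        sd = math.sqrt(scale / h)
        u0 = rng.normal(0.0, sd)
        u1 = rng.normal(0.0, sd)
        y0, y1 = x0 + u0, x1 + u1
        r_new = math.hypot(y0, y1)
        h_new = abs(bond.d2u(r_new)) + eps2
        du = bond.u(r_new) - bond.u(r)
        a = thermal_acceptance(du, h, h_new, u0 * u0 + u1 * u1, scale)
        if rng.uniform() < a:
            x0, x1 = y0, y1
            r = r_new
        out[i] = r
    return out


# ---------------------------------------------------------------------
# membrane relaxation
# ---------------------------------------------------------------------

class MembraneVertexRelax(Rule):
    """Gradient descent of one membrane vertex on the discrete Helfrich
    energy plus any attachment bonds anchored at the vertex; a move that
    would self-intersect the polygon is rejected."""

    name = "membrane_vertex"
    uniform_group = True

    def members(self, state: SimState):
        from .engine import cached
        return cached(state, "mem_vertices",
                      lambda: [("v", vid) for vid in state.membrane.order])

    def member_propensity(self, state: SimState) -> float:
        return state.params.raw["k_kinetic"]

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_kinetic"]
        return [RuleInstance(self, key, k) for key in self.members(state)]

    def is_valid(self, state: SimState, inst: RuleInstance) -> bool:
        return inst.key[1] in state.membrane.pos

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        vid = inst.key[1]
        p = state.params
        poly = state.membrane
        idx = poly.index_of(vid)
        grad = helfrich_gradient(poly, idx, p.kappa_int,
                                 p.raw["mem_area_coeff"],
                                 p.raw["mem_length_coeff"])
        xv = poly.pos[vid]
        for att in state.attachments.values():
            if att.vertex_id != vid:
                continue
            node = state.graph.nodes.get(att.end_id)
            if node is None:
                continue
            bond = Bond(p.eps_lj_int, att.rest_length, p.raw["eps_clip"])
            grad = grad + radial_gradient(xv, [Edge(node.x, bond)])
        delta = -grad / (p.zeta_mem_int * p.raw["k_kinetic"])
        old = xv.copy()
        poly.move_vertex(vid, xv + delta)
        if not poly.is_simple():
            poly.move_vertex(vid, old)   # reject: no state change


def kinetic_rules() -> list[Rule]:
    return [
        BucklingEnd(), BucklingInterior(), BucklingBranch(),
        AngleBendingCenter(), AngleBendingFirst(), AngleBendingLast(),
        ThermalNoise(), MembraneVertexRelax(),
    ]
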