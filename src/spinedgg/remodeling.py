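"""Biochemical rewrite rules: polymerization, nucleotide dynamics,
Arp2/3 branching, capping, cofilin, CaMKII-beta bundling, breaking and
Aip1 severing.

Rate bookkeeping follows the coarse-graining convention: one node is
``N_CG`` monomers, elongation propensities are the per-monomer rate
times concentration divided by ``N_CG`` (one object added per firing
preserves monomer flux), and retraction propensities are the
composition-weighted per-monomer off rate of the end object (one object
removed per firing).  Concentration-bearing rates are converted to
per-second propensities through the pools module using the current
membrane area.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .engine import Rule, RuleInstance, SimState
from .graph import ActinNode
from .membrane import find_crossing, find_crossings_batch, ratchet_factor
from .mechanics import Bond

MIN_PARTIAL_STEP = 0.25   # floor on an adaptive (membrane-gap) step length


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length direction")
    return v / n


def new_node_occupancy(state: SimState, n_mono: int) -> dict[str, int]:
    """Nucleotide composition of a freshly polymerized object, sampled
    from the (ATP-loaded) free pool composition."""
    f_atp = state.params.raw["f_atp_free"]
    n_atp = int(round(f_atp * n_mono))
    return {"n_atp": n_atp, "n_adp": n_mono - n_atp, "n_adp_pi": 0}


def elongation_context(state: SimState, nid: int) -> Optional[int]:
    """The upstream context node x1 for an end at x2 (filament parent or,
    for a one-node daughter, its junction)."""
    prev = state.graph.filament_prev(nid)
    if prev is None:
        prev = state.graph.branch_parent(nid)
    return prev


def barbed_load(state: SimState, nid: int, direction: np.ndarray) -> float:
    """Compressive membrane load (kT/unit) on an attached barbed end,
    projected on the filament axis: the inward push of the attachment
    bond when the bond is shorter than its rest length."""
    att = state.attachment_for_end(nid)
    if att is None:
        return 0.0
    xv = state.membrane.pos.get(att.vertex_id)
    if xv is None:
        return 0.0
    node = state.graph.nodes[nid]
    gap = xv - node.x
    r = float(np.linalg.norm(gap))
    if r < 1e-12:
        return float("inf")
    bond = Bond(state.params.eps_lj_int, att.rest_length,
                state.params.raw["eps_clip"])
    f = -bond.du(r)          # >0 when compressed (repulsive)
    if f <= 0.0:
        return 0.0
    return f * max(0.0, float(np.dot(gap / r, direction)))


class BarbedElongation(Rule):
    """Add one object at an uncapped barbed end; Brownian-ratchet gated
    when the end is attached to the membrane."""

    name = "barbed_elongation"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        if state.pools.counts["actin"] < p.n_cg:
            return []
        conc = state.pools.concentration("actin", state.area)
        base = p.raw["k_barbed_on_ATP"] * conc / p.n_cg
        out = []
        for nid in sorted(state.graph.nodes):
            node = state.graph.nodes[nid]
            if node.next_id is not None or node.capped:
                continue
            ctx = elongation_context(state, nid)
            if ctx is None:
                continue
            a = base
            att = state.attachment_for_end(nid)
            if att is not None:
                direction = _unit(node.x - state.graph.nodes[ctx].x)
                xv = state.membrane.pos.get(att.vertex_id)
                gap = float(np.linalg.norm(xv - node.x)) if xv is not None else 1.0
                delta = min(1.0, max(gap, MIN_PARTIAL_STEP))
                a *= ratchet_factor(barbed_load(state, nid, direction), delta)
            if a > 0.0:
                out.append(RuleInstance(self, (nid, ctx), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, ctx = inst.key
        g = state.graph
        p = state.params
        node = g.nodes[nid]
        theta = float(state.rng.normal(0.0, p.sigma_theta))
        direction = _unit(node.x - g.nodes[ctx].x)
        att = state.attachment_for_end(nid)
        step_len = 1.0
        if att is not None:
            xv = state.membrane.pos.get(att.vertex_id)
            if xv is not None:
                gap = float(np.linalg.norm(xv - node.x))
                step_len = min(1.0, max(gap, MIN_PARTIAL_STEP))
        step_dir = _rot(theta) @ direction
        # adaptive sub-unit stepping against the membrane: never place a
        # new object outside; shorten the step to just inside the wall
        hit = find_crossing(state.membrane, node.x,
                            node.x + step_len * step_dir)
        if hit is not None:
            step_len = 0.9 * float(np.linalg.norm(hit[1] - node.x))
            if step_len < 0.05:
                return   # no room: firing has no effect
        new_x = node.x + step_len * step_dir
        occ = new_node_occupancy(state, p.n_cg)
        new = g.add_node(ActinNode(g.new_id(), new_x, rest_length=step_len,
                                   **occ))
        g.set_next(nid, new.id)
        if att is not None:
            att.end_id = new.id          # the attachment follows the tip
            node.vertex_ref = None
            new.vertex_ref = att.vertex_id
        state.pools.take("actin", p.n_cg)
        g.refresh_angles_around(nid, new.id)


class BarbedRetraction(Rule):
    """Remove the barbed-end object; the neighbor becomes the new end."""

    name = "barbed_retraction"

    def instances(self, state: SimState) -> list[RuleInstance]:
        from .engine import cached
        p = state.params
        out = []
        chains = cached(state, "chains", state.graph.filaments)
        for chain in chains:
            if len(chain) < 3:
                continue   # the seed dimer persists
            nid = chain[-1]
            node = state.graph.nodes[nid]
            if (node.capped or node.next_id is not None
                    or node.daughter_id is not None):
                continue
            if state.attachment_for_end(nid) is not None:
                continue
            n = node.n_mono
            if n == 0:
                continue
            a = (node.n_atp * p.raw["k_barbed_off_ATP"]
                 + (node.n_adp_pi + node.n_adp) * p.raw["k_barbed_off_ADP"]) / n
            out.append(RuleInstance(self, (nid, chain[-2]), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, neighbor = inst.key
        g = state.graph
        node = g.nodes[nid]
        _release_occupancy(state, node)
        g.set_next(neighbor, None)
        g.remove_node(nid)
        g.refresh_angles_around(neighbor)


class PointedElongation(Rule):
    """Mirror of barbed elongation at the pointed end (reversed angle)."""

    name = "pointed_elongation"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        if state.pools.counts["actin"] < p.n_cg:
            return []
        conc = state.pools.concentration("actin", state.area)
        a = p.raw["k_pointed_on_ATP"] * conc / p.n_cg
        if a <= 0.0:
            return []
        out = []
        for nid in sorted(state.graph.nodes):
            if state.graph.kind(nid) != "pointed_end":
                continue
            nxt = state.graph.nodes[nid].next_id
            if nxt is not None:
                out.append(RuleInstance(self, (nid, nxt), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, nxt = inst.key
        g = state.graph
        p = state.params
        node = g.nodes[nid]
        theta = float(state.rng.normal(0.0, p.sigma_theta))
        direction = _unit(node.x - g.nodes[nxt].x)
        new_x = node.x + _rot(-theta) @ direction
        occ = new_node_occupancy(state, p.n_cg)
        new = g.add_node(ActinNode(g.new_id(), new_x, **occ))
        g.set_next(new.id, nid)
        state.pools.take("actin", p.n_cg)
        g.refresh_angles_around(nid, new.id)


class PointedRetraction(Rule):
    name = "pointed_retraction"

    def instances(self, state: SimState) -> list[RuleInstance]:
        from .engine import cached
        p = state.params
        out = []
        chains = cached(state, "chains", state.graph.filaments)
        for chain in chains:
            if len(chain) < 3:
                continue
            nid = chain[0]
            if state.graph.kind(nid) != "pointed_end":
                continue   # daughter chains start at a branch, not an end
            node = state.graph.nodes[nid]
            n = node.n_mono
            if n == 0:
                continue
            a = (node.n_atp * p.raw["k_pointed_off_ATP"]
                 + (node.n_adp_pi + node.n_adp) * p.raw["k_pointed_off_ADP"]) / n
            out.append(RuleInstance(self, (nid, chain[1]), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, neighbor = inst.key
        g = state.graph
        node = g.nodes[nid]
        _release_occupancy(state, node)
        g.set_next(nid, None)
        g.remove_node(nid)
        g.refresh_angles_around(neighbor)


def _release_occupancy(state: SimState, node: ActinNode) -> None:
    """Return a deleted object's monomers and bound proteins to the pools."""
    state.pools.give("actin", node.n_mono)
    if node.n_cof:
        state.pools.give("cof", node.n_cof)
    if node.aip1:
        state.pools.give("aip1", 1)
    if node.capped == "cap":
        state.pools.give("cap", 1)
    elif node.capped == "aip1":
        state.pools.give("aip1", 1)
    if node.camkii_link is not None:
        link = state.graph.links.get(node.camkii_link)
        if link is not None:
            state.graph.remove_link(link.id)
            state.pools.give("camkii", 1)


class NucleotideHydrolysis(Rule):
    """ATP -> ADP+Pi, one monomer per firing."""

    name = "atp_hydrolysis"

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_atp_hydrolysis"]
        return [RuleInstance(self, (nid,), node.n_atp * k)
                for nid, node in sorted(state.graph.nodes.items())
                if node.n_atp > 0]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        node.n_atp -= 1
        node.n_adp_pi += 1


class PiRelease(Rule):
    """ADP+Pi -> ADP; accelerated when cofilin is bound on the object or
    an adjacent one."""

    name = "pi_release"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        out = []
        for nid, node in sorted(state.graph.nodes.items()):
            if node.n_adp_pi == 0:
                continue
            near_cof = node.n_cof > 0 or any(
                state.graph.nodes[m].n_cof > 0
                for m in state.graph.neighbors(nid))
            k = p.raw["k_cof_pi"] if near_cof else p.raw["k_pi"]
            out.append(RuleInstance(self, (nid,), node.n_adp_pi * k))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        node.n_adp_pi -= 1
        node.n_adp += 1


class BranchNucleation(Rule):
    """Arp2/3 nucleates a daughter filament at ~70 degrees off the parent;
    mutually exclusive with bound cofilin on the parent node."""

    name = "branch_nucleation"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        if (state.pools.counts["arp23"] < 1
                or state.pools.counts["actin"] < p.n_cg):
            return []
        a = p.raw["k_branch"] * state.pools.concentration("arp23", state.area)
        if a <= 0.0:
            return []
        out = []
        for nid in sorted(state.graph.nodes):
            node = state.graph.nodes[nid]
            if node.daughter_id is not None or node.n_cof > 0:
                continue
            ctx = state.graph.filament_prev(nid)
            if ctx is None:
                continue
            out.append(RuleInstance(self, (nid, ctx), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, ctx = inst.key
        g = state.graph
        p = state.params
        node = g.nodes[nid]
        s = 1.0 if state.rng.uniform() < 0.5 else -1.0
        theta = float(state.rng.normal(s * p.raw["theta_arp"], p.sigma_theta))
        direction = _unit(node.x - g.nodes[ctx].x)
        new_x = node.x + _rot(theta) @ direction
        occ = new_node_occupancy(state, p.n_cg)
        daughter = g.add_node(ActinNode(g.new_id(), new_x, **occ))
        g.set_daughter(nid, daughter.id)
        state.pools.take("arp23", 1)
        state.pools.take("actin", p.n_cg)
        g.refresh_angles_around(nid, daughter.id)


class Debranch(Rule):
    """Arp2/3 dissociates from the parent; cofilin occupancy on and next
    to the junction accelerates it (x50 at full occupancy)."""

    name = "debranch"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        out = []
        for nid in sorted(state.graph.nodes):
            node = state.graph.nodes[nid]
            if node.daughter_id is None:
                continue
            c = node.cof_fraction
            nbrs = [m for m in state.graph.neighbors(nid)
                    if m != node.daughter_id]
            c_adj = (sum(state.graph.nodes[m].cof_fraction for m in nbrs)
                     / len(nbrs)) if nbrs else 0.0
            a = p.raw["k_debranch"] * (
                1.0 + p.raw["sigma_comp"] * c + p.raw["k_comp"] * c_adj)
            out.append(RuleInstance(self, (nid, node.daughter_id), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid, daughter = inst.key
        g = state.graph
        g.set_daughter(nid, None)
        state.pools.give("arp23", 1)
        g.refresh_angles_around(nid, daughter)


class Cap(Rule):
    name = "cap"

    def instances(self, state: SimState) -> list[RuleInstance]:
        if state.pools.counts["cap"] < 1:
            return []
        a = (state.params.raw["k_cap_on"]
             * state.pools.concentration("cap", state.area))
        return [RuleInstance(self, (nid,), a)
                for nid, node in sorted(state.graph.nodes.items())
                if node.next_id is None and node.daughter_id is None
                and node.capped is None]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        state.graph.nodes[inst.key[0]].capped = "cap"
        state.pools.take("cap", 1)


class Uncap(Rule):
    """Cap release; the same off rate serves the Aip1 end cap."""

    name = "uncap"

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_cap_off"]
        return [RuleInstance(self, (nid,), k)
                for nid, node in sorted(state.graph.nodes.items())
                if node.capped is not None]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        state.pools.give("cap" if node.capped == "cap" else "aip1", 1)
        node.capped = None


class CofilinBindBare(Rule):
    """Slow, isolated ("cof-S") cofilin binding to a fully-ADP object."""

    name = "cofilin_bind_bare"

    def instances(self, state: SimState) -> list[RuleInstance]:
        if state.pools.counts["cof"] < 1:
            return []
        a = (state.params.raw["k_single_on_cof"]
             * state.pools.concentration("cof", state.area))
        out = []
        for nid, node in sorted(state.graph.nodes.items()):
            if (node.n_mono > 0 and node.n_atp == 0
                    and node.n_cof == 0 and node.camkii_link is None):
                out.append(RuleInstance(self, (nid,), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        node.cof_single = True
        node.n_cof = 1
        state.pools.take("cof", 1)


class CofilinBindAccel1(Rule):
    """A lone bound cofilin recruits neighbors cooperatively within the
    object (two available directions -> x2), converting it to cofilactin."""

    name = "cofilin_bind_accel_1"

    def instances(self, state: SimState) -> list[RuleInstance]:
        out = []
        for nid, node in sorted(state.graph.nodes.items()):
            if not node.cof_single:
                continue
            need = node.n_mono - node.n_cof
            if state.pools.counts["cof"] < need:
                continue
            a = 2.0 * (state.params.raw["k_cof_on_edge_ADP"]
                       * state.pools.concentration("cof", state.area))
            if a > 0.0:
                out.append(RuleInstance(self, (nid,), a))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        state.pools.take("cof", node.n_mono - node.n_cof)
        node.n_cof = node.n_mono
        node.cof_single = False


class CofilinBindAccel2(Rule):
    """Cofilin spreads to a bare fully-ADP object from an adjacent
    cofilactin object; doubled when flanked on both sides."""

    name = "cofilin_bind_accel_2"

    def instances(self, state: SimState) -> list[RuleInstance]:
        base = (state.params.raw["k_cof_on_edge_ADP"]
                * state.pools.concentration("cof", state.area))
        if base <= 0.0:
            return []
        out = []
        for nid, node in sorted(state.graph.nodes.items()):
            if (node.n_mono == 0 or node.n_atp > 0
                    or node.n_cof > 0 or node.camkii_link is not None):
                continue
            if state.pools.counts["cof"] < node.n_mono:
                continue
            n_sources = sum(
                1 for m in state.graph.neighbors(nid)
                if state.graph.nodes[m].n_cof == state.graph.nodes[m].n_mono
                and state.graph.nodes[m].n_mono > 0)
            if n_sources:
                out.append(RuleInstance(self, (nid,), base * n_sources))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        state.pools.take("cof", node.n_mono)
        node.n_cof = node.n_mono


class CofilinUnbind(Rule):
    """One cofilin unit leaves per firing, at k_cof_off per bound unit."""

    name = "cofilin_unbind"

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_cof_off"]
        return [RuleInstance(self, (nid,), node.n_cof * k)
                for nid, node in sorted(state.graph.nodes.items())
                if node.n_cof > 0]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        node = state.graph.nodes[inst.key[0]]
        node.n_cof -= 1
        state.pools.give("cof", 1)
        if node.n_cof == 0:
            node.cof_single = False
            if node.aip1:        # Aip1 only stays on cofilactin
                node.aip1 = False
                state.pools.give("aip1", 1)


def filament_direction(state: SimState, nid: int) -> Optional[np.ndarray]:
    """Local filament axis at a node (unit vector), if defined."""
    g = state.graph
    node = g.nodes[nid]
    prev = g.filament_prev(nid)
    a = g.nodes[prev].x if prev is not None else node.x
    b = g.nodes[node.next_id].x if node.next_id is not None else node.x
    d = b - a
    n = float(np.linalg.norm(d))
    return d / n if n > 0 else None


class CamkiiBind(Rule):
    """CaMKII-beta bundles two nearby, nearly parallel, non-adjacent
    objects on distinct filaments (Heaviside distance/angle gates)."""

    name = "camkii_bind"

    def instances(self, state: SimState) -> list[RuleInstance]:
        p = state.params
        if state.pools.counts["camkii"] < 1:
            return []
        base = (p.raw["k_camkii_on"]
                * state.pools.concentration("camkii", state.area))
        if base <= 0.0:
            return []
        from .engine import cached
        g = state.graph
        cand = [nid for nid, node in sorted(g.nodes.items())
                if node.camkii_link is None and node.n_cof == 0
                and node.n_mono > 0]
        if len(cand) < 2:
            return []

        def _fil_of() -> dict[int, int]:
            out = {}
            for fi, chain in enumerate(g.filaments()):
                for nid in chain:
                    out[nid] = fi
            return out

        fil_of = cached(state, "fil_of", _fil_of)
        dirs_arr = np.zeros((len(cand), 2))
        has_dir = np.zeros(len(cand), dtype=bool)
        for i, nid in enumerate(cand):
            d = filament_direction(state, nid)
            if d is not None:
                dirs_arr[i] = d
                has_dir[i] = True
        xs = np.array([g.nodes[n].x for n in cand])
        diff = xs[:, None, :] - xs[None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        cos_min = math.cos(p.raw["theta_bundle"])
        cosang = np.abs(dirs_arr @ dirs_arr.T)
        iu = np.triu_indices(len(cand), k=1)
        mask = ((dist2[iu] <= p.du_camkii_int ** 2)
                & (cosang[iu] >= cos_min)
                & has_dir[iu[0]] & has_dir[iu[1]])
        out = []
        for i, j in zip(iu[0][mask], iu[1][mask]):
            a_id, b_id = cand[int(i)], cand[int(j)]
            if fil_of.get(a_id) == fil_of.get(b_id):
                continue
            if b_id in g.neighbors(a_id):
                continue
            out.append(RuleInstance(self, (a_id, b_id), base))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        a_id, b_id = inst.key
        g = state.graph
        rest = float(np.linalg.norm(g.nodes[a_id].x - g.nodes[b_id].x))
        g.add_link(a_id, b_id, rest)
        state.pools.take("camkii", 1)


class CamkiiUnbind(Rule):
    name = "camkii_unbind"

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_camkii_off"]
        return [RuleInstance(self, ("link", lid), k)
                for lid in sorted(state.graph.links)]

    def is_valid(self, state: SimState, inst: RuleInstance) -> bool:
        return inst.key[1] in state.graph.links

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        state.graph.remove_link(inst.key[1])
        state.pools.give("camkii", 1)


class BreakFilament(Rule):
    """Cut a filament edge when a stored bend angle exceeds the breaking
    threshold for its cofilin state: bare actin 57deg, cofilactin 73deg,
    cofilactin-actin boundary 31deg (a disjunction over the two edge
    nodes, each with its own threshold)."""

    name = "break_filament"

    def _gate(self, state: SimState, i: int, j: int) -> bool:
        p = state.params
        ni, nj = state.graph.nodes[i], state.graph.nodes[j]
        ci, cj = ni.n_cof > 0, nj.n_cof > 0
        if ci != cj:
            thr_i = thr_j = p.raw["theta_break_boundary"]
        else:
            thr_i = p.raw["theta_break_cofilactin"] if ci \
                else p.raw["theta_break_actin"]
            thr_j = p.raw["theta_break_cofilactin"] if cj \
                else p.raw["theta_break_actin"]
        return abs(ni.theta) >= thr_i or abs(nj.theta) >= thr_j

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_break"]
        out = []
        for i in sorted(state.graph.nodes):
            j = state.graph.nodes[i].next_id
            if j is not None and self._gate(state, i, j):
                out.append(RuleInstance(self, (i, j), k))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        i, j = inst.key
        g = state.graph
        g.set_next(i, None)
        g.refresh_angles_around(i, j)


class Aip1Bind(Rule):
    """Aip1 binds cofilactin (cofilin-decorated) objects."""

    name = "aip1_bind"

    def instances(self, state: SimState) -> list[RuleInstance]:
        if state.pools.counts["aip1"] < 1:
            return []
        a = (state.params.raw["k_on_aip1"]
             * state.pools.concentration("aip1", state.area))
        return [RuleInstance(self, (nid,), a)
                for nid, node in sorted(state.graph.nodes.items())
                if node.n_cof > 0 and not node.aip1]

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        state.graph.nodes[inst.key[0]].aip1 = True
        state.pools.take("aip1", 1)


class Aip1Sever(Rule):
    """Severing at a bound Aip1, with no angle condition: the upstream
    piece gains an Aip1-capped barbed end, the downstream piece a new
    pointed end."""

    name = "aip1_sever"

    def instances(self, state: SimState) -> list[RuleInstance]:
        k = state.params.raw["k_sever"]
        out = []
        for nid, node in sorted(state.graph.nodes.items()):
            if node.aip1 and state.graph.filament_prev(nid) is not None:
                out.append(RuleInstance(self, (nid,), k))
        return out

    def execute(self, state: SimState, inst: RuleInstance) -> None:
        nid = inst.key[0]
        g = state.graph
        prev = g.filament_prev(nid)
        node = g.nodes[nid]
        g.set_next(prev, None)
        g.nodes[prev].capped = "aip1"   # Aip1 relocates onto the new end
        node.aip1 = False
        g.refresh_angles_around(prev, nid)


# ---------------------------------------------------------------------
# actin-membrane maintenance (runs after every event)
# ---------------------------------------------------------------------

def attach_intersecting_ends(state: SimState) -> None:
    """Attach any uncapped barbed end whose segment, pseudo-extended by
    the overgrowth length, crosses a membrane edge: a new vertex is
    inserted at the crossing and an attachment object created."""
    og = state.params.raw["overgrowth_length"]
    g = state.graph
    attached = {att.end_id for att in state.attachments.values()}
    probes = []
    for nid in sorted(g.nodes):
        node = g.nodes[nid]
        if node.next_id is not None or node.capped or nid in attached:
            continue
        ctx = elongation_context(state, nid)
        if ctx is None:
            continue
        direction = _unit(node.x - g.nodes[ctx].x)
        # probe the rod itself plus the pseudo-extended overgrowth reach
        probes.append((nid, g.nodes[ctx].x, node.x + og * direction))
    if not probes:
        return
    hits = find_crossings_batch(state.membrane,
                                np.array([p[1] for p in probes]),
                                np.array([p[2] for p in probes]))
    for (nid, _, _), hit in zip(probes, hits):
        if hit is None:
            continue
        # re-resolve against the current polygon: an earlier attachment
        # in this pass may have inserted a vertex and shifted indices
        node = g.nodes[nid]
        ctx = elongation_context(state, nid)
        direction = _unit(node.x - g.nodes[ctx].x)
        cur = find_crossing(state.membrane, g.nodes[ctx].x,
                            node.x + og * direction)
        if cur is None:
            continue
        edge_idx, point = cur
        vid = state.membrane.insert_vertex(edge_idx, point)
        rest = float(np.clip(np.linalg.norm(point - node.x),
                             MIN_PARTIAL_STEP, 1.0))
        att = state.new_attachment(nid, vid, rest)
        node.vertex_ref = att.vertex_id


def detach_far_ends(state: SimState) -> None:
    """Remove attachments whose end has retracted or drifted beyond the
    interaction range (2 * r_min); the inserted vertex is retained."""
    for aid in sorted(state.attachments):
        att = state.attachments[aid]
        node = state.graph.nodes.get(att.end_id)
        xv = state.membrane.pos.get(att.vertex_id)
        drop = node is None or xv is None
        if not drop:
            drop = float(np.linalg.norm(node.x - xv)) > 2.0 * state.params.r_min
        if drop:
            if node is not None:
                node.vertex_ref = None
            del state.attachments[aid]


def remodeling_rules() -> list[Rule]:
    """The full biochemical rule set, in a stable order."""
    return [
        BarbedElongation(), BarbedRetraction(),
        PointedElongation(), PointedRetraction(),
        NucleotideHydrolysis(), PiRelease(),
        BranchNucleation(), Debranch(),
        Cap(), Uncap(),
        CofilinBindBare(), CofilinBindAccel1(), CofilinBindAccel2(),
        CofilinUnbind(),
        CamkiiBind(), CamkiiUnbind(),
        BreakFilament(), Aip1Bind(), Aip1Sever(),
    ]
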