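"""Lossless structured-text snapshots of a simulation state, GraphML
export of the cytoskeleton graph, and CSV export of the membrane
polyline.

The snapshot is plain JSON: node records (id, kind, position, pointers,
occupancy, stored angles), membrane vertices in CCW order, attachments,
pools, clock, the full parameter set and the RNG bit-generator state,
so a run continued from a snapshot is bit-identical to an uninterrupted
one.
"""

from __future__ import annotations

import json
from typing import Optional

import networkx as nx
import numpy as np

from .engine import SimState
from .graph import ActinNode, BundleLink, LabeledGraph
from .membrane import Attachment, MembranePolygon
from .params import Params, _validated
from .pools import SpeciesPools

_NODE_FIELDS = ("next_id", "daughter_id", "theta", "theta_branch",
                "n_atp", "n_adp_pi", "n_adp", "n_cof", "cof_single",
                "aip1", "camkii_link", "capped", "vertex_ref", "rest_length")


def state_to_dict(state: SimState) -> dict:
    g = state.graph
    return {
        "format": "spinedgg-snapshot-1",
        "time": state.time,
        "parameters": dict(state.params.raw),
        "nodes": [
            {"id": nid, "kind": g.kind(nid),
             "x": [float(v) for v in g.nodes[nid].x],
             **{f: getattr(g.nodes[nid], f) for f in _NODE_FIELDS}}
            for nid in sorted(g.nodes)],
        "links": [
            {"id": l.id, "node_a": l.node_a, "node_b": l.node_b,
             "rest_length": l.rest_length}
            for l in (g.links[k] for k in sorted(g.links))],
        "membrane": {
            "order": list(state.membrane.order),
            "positions": {str(vid): [float(v) for v in pos]
                          for vid, pos in state.membrane.pos.items()},
        },
        "attachments": [
            {"id": a.id, "end_id": a.end_id, "vertex_id": a.vertex_id,
             "rest_length": a.rest_length, "created": a.created}
            for a in (state.attachments[k]
                      for k in sorted(state.attachments))],
        "pools": {"counts": dict(state.pools.counts),
                  "stimulated": state.pools.stimulated},
        "rng_state": _jsonable(state.rng.bit_generator.state),
        "next_attachment_id": state._next_attachment_id,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_snapshot(state: SimState, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(state_to_dict(state), fh, indent=1)


def state_from_dict(data: dict, with_rules: bool = True) -> SimState:
    from .fixtures import build_state   # deferred: fixtures imports engine

    params = _validated(data["parameters"])
    g = LabeledGraph()
    for rec in data["nodes"]:
        kwargs = {f: rec[f] for f in _NODE_FIELDS
                  if f not in ("next_id", "daughter_id")}
        g.add_node(ActinNode(rec["id"], np.array(rec["x"], dtype=float),
                             **kwargs))
    for rec in data["nodes"]:
        if rec["next_id"] is not None:
            g.set_next(rec["id"], rec["next_id"])
        if rec["daughter_id"] is not None:
            g.set_daughter(rec["id"], rec["daughter_id"])
    for rec in data["links"]:
        link = BundleLink(rec["id"], rec["node_a"], rec["node_b"],
                          rec["rest_length"])
        g.links[link.id] = link
        g._next_link_id = max(g._next_link_id, link.id + 1)
    mem = data["membrane"]
    order = mem["order"]
    coords = np.array([mem["positions"][str(v)] for v in order])
    poly = MembranePolygon.__new__(MembranePolygon)
    poly.order = list(order)
    poly.pos = {int(v): np.array(mem["positions"][str(v)], dtype=float)
                for v in mem["positions"]}
    poly._next_id = max(poly.pos) + 1 if poly.pos else 0
    poly._shape_cache = None
    poly._coords_cache = None
    assert coords.shape[1] == 2
    state = build_state(params, g, poly, seed=0, with_rules=with_rules,
                        stimulated=data["pools"]["stimulated"])
    state.pools.counts = dict(data["pools"]["counts"])
    state.time = data["time"]
    for rec in data["attachments"]:
        att = Attachment(rec["id"], rec["end_id"], rec["vertex_id"],
                         rec["rest_length"], rec["created"])
        state.attachments[att.id] = att
    state._next_attachment_id = data["next_attachment_id"]
    state.rng.bit_generator.state = data["rng_state"]
    return state


def read_snapshot(path: str, with_rules: bool = True) -> SimState:
    with open(path) as fh:
        return state_from_dict(json.load(fh), with_rules=with_rules)


def to_graphml(state: SimState, path: Optional[str] = None) -> nx.DiGraph:
    """Cytoskeleton graph (next/daughter pointers + bundle links) for
    external viewers."""
    g = nx.DiGraph()
    for nid in sorted(state.graph.nodes):
        node = state.graph.nodes[nid]
        g.add_node(nid, kind=state.graph.kind(nid),
                   x=float(node.x[0]), y=float(node.x[1]),
                   theta=node.theta, n_cof=node.n_cof)
    for nid in sorted(state.graph.nodes):
        node = state.graph.nodes[nid]
        if node.next_id is not None:
            g.add_edge(nid, node.next_id, kind="next")
        if node.daughter_id is not None:
            g.add_edge(nid, node.daughter_id, kind="daughter")
    for link in state.graph.links.values():
        g.add_edge(link.node_a, link.node_b, kind="bundle")
    if path is not None:
        nx.write_graphml(g, path)
    return g


def membrane_to_csv(state: SimState, path: str) -> None:
    """Closed CCW polyline as plain x,y rows (first vertex repeated)."""
    coords = state.membrane.coords()
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in list(coords) + [coords[0]]:
            fh.write(f"{x!r},{y!r}\n")
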