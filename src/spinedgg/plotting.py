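"""Basic state rendering: membrane polygon, actin objects colored by
local bending energy, barbed ends, junctions, caps and bundle links."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import SimState
from .kinetics import effective_k_bend, triple_target
from .mechanics import angle_energy


def node_bending_energy(state: SimState, nid: int) -> float:
    """Summed angle-bending energy (kT) of the triples centered here."""
    g = state.graph
    total = 0.0
    for (i, j, k) in g.triples():
        if j != nid:
            continue
        total += angle_energy(g.nodes[i].x, g.nodes[j].x, g.nodes[k].x,
                              triple_target(state, i, j, k),
                              effective_k_bend(state, j))
    return total


def render(state: SimState, path: str, dpi: int = 110) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    mem = state.membrane.coords()
    closed = np.vstack([mem, mem[:1]])
    ax.plot(closed[:, 0], closed[:, 1], "-", color="0.35", lw=1.2,
            label="membrane")
    g = state.graph
    if g.nodes:
        energies = {nid: node_bending_energy(state, nid) for nid in g.nodes}
        emax = max(max(energies.values()), 1e-12)
        cmap = plt.get_cmap("viridis")
        for nid in sorted(g.nodes):
            node = g.nodes[nid]
            for child in (node.next_id, node.daughter_id):
                if child is not None:
                    seg = np.array([node.x, g.nodes[child].x])
                    ax.plot(seg[:, 0], seg[:, 1], "-", color="0.6", lw=0.8)
            kind = g.kind(nid)
            if kind == "barbed_end":
                color, marker = "green", "o"
            elif kind == "capped_end":
                color, marker = "red", "s"
            elif kind == "junction":
                color, marker = "black", "^"
            else:
                color = cmap(min(energies[nid] / emax, 1.0))
                marker = "o"
            ax.plot(*node.x, marker, color=color, ms=4)
        for link in g.links.values():
            seg = np.array([g.nodes[link.node_a].x, g.nodes[link.node_b].x])
            ax.plot(seg[:, 0], seg[:, 1], ":", color="purple", lw=1.0)
    for att in state.attachments.values():
        node = g.nodes.get(att.end_id)
        xv = state.membrane.pos.get(att.vertex_id)
        if node is not None and xv is not None:
            seg = np.array([node.x, xv])
            ax.plot(seg[:, 0], seg[:, 1], "--", color="orange", lw=0.8)
    ax.set_aspect("equal")
    ax.set_title(f"t = {state.time:.3f} s, "
                 f"{len(g.nodes)} objects, "
                 f"area = {state.area:.2f} units$^2$")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
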