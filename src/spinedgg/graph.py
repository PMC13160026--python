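"""Typed labelled graph for the coarse-grained actin cytoskeleton.

Each :class:`ActinNode` stands for ``N_CG`` actin monomers.  Filament
topology is stored as "next" pointers running toward the barbed end;
junction nodes additionally carry a ``daughter_id`` pointer to the first
node of an Arp2/3-nucleated branch.  Node kind (barbed end, pointed end,
interior, junction, capped end) is derived from connectivity and the cap
flag rather than stored, which keeps the kind invariants true by
construction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional

import numpy as np

ATP, ADP_PI, ADP = "ATP", "ADP_Pi", "ADP"


@dataclasses.dataclass
class ActinNode:
    id: int
    x: np.ndarray                      # 2D position, internal units
    next_id: Optional[int] = None      # toward the barbed end
    daughter_id: Optional[int] = None  # branch pointer (junctions only)
    theta: float = 0.0                 # stored middle bend angle (rad)
    theta_branch: float = 0.0          # stored branch angle (junctions)
    n_atp: int = 0
    n_adp_pi: int = 0
    n_adp: int = 0
    n_cof: int = 0                     # cofilin-bound monomers
    cof_single: bool = False           # lone "cof-S" seed
    aip1: bool = False                 # Aip1 bound (requires cofilin)
    camkii_link: Optional[int] = None  # BundleLink id
    capped: Optional[str] = None       # None | "cap" | "aip1"
    vertex_ref: Optional[int] = None   # membrane attachment id (ends only)
    rest_length: float = 1.0           # equilibrium segment length

    @property
    def n_mono(self) -> int:
        return self.n_atp + self.n_adp_pi + self.n_adp

    @property
    def cof_fraction(self) -> float:
        return self.n_cof / self.n_mono if self.n_mono else 0.0


@dataclasses.dataclass
class BundleLink:
    """CaMKII-beta cross-link between two non-adjacent actin nodes."""

    id: int
    node_a: int
    node_b: int
    rest_length: float


class LabeledGraph:
    """Node store plus adjacency queries for the cytoskeleton graph."""

    def __init__(self) -> None:
        self.nodes: dict[int, ActinNode] = {}
        self.links: dict[int, BundleLink] = {}
        # reverse pointers: a node has at most one next-parent (the node
        # whose next pointer targets it) and one branch parent
        self._next_parent: dict[int, int] = {}
        self._branch_parent: dict[int, int] = {}
        self._next_id = 0
        self._next_link_id = 0

    # -- construction -------------------------------------------------
    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def add_node(self, node: ActinNode) -> ActinNode:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id}")
        self._next_id = max(self._next_id, node.id + 1)
        self.nodes[node.id] = node
        if node.next_id is not None:
            self._register_parent(self._next_parent, node.next_id, node.id)
        if node.daughter_id is not None:
            self._register_parent(self._branch_parent, node.daughter_id,
                                  node.id)
        return node

    def _register_parent(self, table: dict[int, int], child: int,
                         parent: int) -> None:
        self._check_live(child)
        if child in table:
            raise ValueError(f"node {child} already has a parent pointer "
                             f"from {table[child]}")
        table[child] = parent

    def remove_node(self, nid: int) -> ActinNode:
        if nid in self._next_parent or nid in self._branch_parent:
            src_id = self._next_parent.get(nid, self._branch_parent.get(nid))
            raise ValueError(f"removing node {nid} leaves a dangling pointer "
                             f"from {src_id}")
        node = self.nodes.pop(nid)
        if node.next_id is not None:
            self._next_parent.pop(node.next_id, None)
        if node.daughter_id is not None:
            self._branch_parent.pop(node.daughter_id, None)
        return node

    def set_next(self, nid: int, target: Optional[int]) -> None:
        node = self.nodes[nid]
        if node.next_id is not None:
            self._next_parent.pop(node.next_id, None)
        if target is not None:
            self._register_parent(self._next_parent, target, nid)
        node.next_id = target

    def set_daughter(self, nid: int, target: Optional[int]) -> None:
        node = self.nodes[nid]
        if node.daughter_id is not None:
            self._branch_parent.pop(node.daughter_id, None)
        if target is not None:
            self._register_parent(self._branch_parent, target, nid)
        node.daughter_id = target

    def add_link(self, a: int, b: int, rest_length: float) -> BundleLink:
        if b in self.neighbors(a):
            raise ValueError("bundle link requires non-adjacent nodes")
        link = BundleLink(self._next_link_id, a, b, rest_length)
        self._next_link_id += 1
        self.links[link.id] = link
        self.nodes[a].camkii_link = link.id
        self.nodes[b].camkii_link = link.id
        return link

    def remove_link(self, link_id: int) -> BundleLink:
        link = self.links.pop(link_id)
        for nid in (link.node_a, link.node_b):
            if nid in self.nodes and self.nodes[nid].camkii_link == link_id:
                self.nodes[nid].camkii_link = None
        return link

    def _check_live(self, nid: int) -> None:
        if nid not in self.nodes:
            raise ValueError(f"pointer target {nid} is not a live node")

    # -- queries ------------------------------------------------------
    def prev_ids(self, nid: int) -> list[int]:
        """Nodes whose next/daughter pointer targets ``nid``."""
        a = self._next_parent.get(nid)
        b = self._branch_parent.get(nid)
        if a is None:
            return [] if b is None else [b]
        if b is None:
            return [a]
        return [a, b] if a <= b else [b, a]

    def filament_prev(self, nid: int) -> Optional[int]:
        """The upstream node along the same filament (next-pointer parent)."""
        return self._next_parent.get(nid)

    def branch_parent(self, nid: int) -> Optional[int]:
        """The junction whose daughter pointer targets ``nid``."""
        return self._branch_parent.get(nid)

    def neighbors(self, nid: int) -> list[int]:
        """All graph-adjacent node ids (filament edges both ways + branch)."""
        node = self.nodes[nid]
        out = [t for t in (node.next_id, node.daughter_id) if t is not None]
        out.extend(self.prev_ids(nid))
        return sorted(set(out))

    def kind(self, nid: int) -> str:
        node = self.nodes[nid]
        if node.daughter_id is not None:
            return "junction"
        if node.next_id is None:
            return "capped_end" if node.capped else "barbed_end"
        if self.filament_prev(nid) is None and self.branch_parent(nid) is None:
            return "pointed_end"
        return "interior"

    def is_end(self, nid: int) -> bool:
        return self.kind(nid) in ("barbed_end", "pointed_end", "capped_end")

    def triples(self) -> Iterator[tuple[int, int, int]]:
        """All directed length-3 paths i->j->k, ascending in (j, i, k).

        A junction contributes the triples through both its continuation
        and its daughter edge.
        """
        for j in sorted(self.nodes):
            node_j = self.nodes[j]
            preds = self.prev_ids(j)
            succs = [t for t in (node_j.next_id, node_j.daughter_id)
                     if t is not None]
            for i in preds:
                for k in succs:
                    yield (i, j, k)

    def filaments(self) -> list[list[int]]:
        """Node chains from each filament start to its barbed end."""
        starts = [nid for nid in self.nodes
                  if self.filament_prev(nid) is None
                  and self.branch_parent(nid) is None]
        # daughters start at the junction's daughter pointer
        for node in self.nodes.values():
            if node.daughter_id is not None:
                starts.append(node.daughter_id)
        chains = []
        for start in sorted(set(starts)):
            chain, cur = [], start
            seen = set()
            while cur is not None and cur not in seen:
                chain.append(cur)
                seen.add(cur)
                cur = self.nodes[cur].next_id
            chains.append(chain)
        return chains

    def total_monomers(self) -> int:
        return sum(n.n_mono for n in self.nodes.values())

    def refresh_angles(self, ids: set[int] | None = None) -> None:
        """Recompute stored bend angles from geometry for the given nodes
        (and nothing else); ``None`` refreshes every node.

        Stored angles are caches: rules read them (breaking gate) instead
        of recomputing all angles each iteration, so every rule that
        moves or rewires nodes must refresh the affected neighborhood.
        """
        from .mechanics import bend_angle  # local import: no cycle at load

        for nid in sorted(ids if ids is not None else self.nodes):
            if nid not in self.nodes:
                continue
            node = self.nodes[nid]
            prev = self.filament_prev(nid)
            if prev is None:
                prev = self.branch_parent(nid)
            if prev is not None and node.next_id is not None:
                node.theta = bend_angle(self.nodes[prev].x, node.x,
                                        self.nodes[node.next_id].x)
            else:
                node.theta = 0.0
            if node.daughter_id is not None and prev is not None:
                node.theta_branch = bend_angle(
                    self.nodes[prev].x, node.x,
                    self.nodes[node.daughter_id].x)
            else:
                node.theta_branch = 0.0

    def refresh_angles_around(self, *ids: int) -> None:
        affected = set()
        for nid in ids:
            if nid in self.nodes:
                affected.add(nid)
                affected.update(self.neighbors(nid))
        self.refresh_angles(affected)

    def check_invariants(self) -> None:
        """Raise AssertionError on any violated structural invariant."""
        for nid, node in self.nodes.items():
            for tgt in (node.next_id, node.daughter_id):
                assert tgt is None or tgt in self.nodes, \
                    f"dangling pointer {nid}->{tgt}"
            assert node.n_mono >= 0 and node.n_cof <= node.n_mono
            assert not node.aip1 or node.n_cof > 0, \
                "Aip1 requires bound cofilin"
            if self.is_end(nid):
                assert node.theta == 0.0, "end nodes carry zero stored angle"
            if node.daughter_id is not None:
                # canonical junction: continuation + daughter; the
                # continuation may have been broken or retracted away,
                # leaving the branch point at a filament end
                assert node.daughter_id in self.nodes
        for link in self.links.values():
            assert link.node_a in self.nodes and link.node_b in self.nodes
            assert link.node_b not in self.neighbors(link.node_a), \
                "bundle link joins adjacent nodes"
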