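"""The enclosing membrane: a counterclockwise polygon in 2D.

The spine head surface is represented by a simple closed polygon whose
vertices move by gradient descent on the discrete Helfrich bending
energy

    U_mem = 2 kappa * sum_i  H_i^2 z_i,

where ``H_i`` is the finite-difference mean curvature at vertex i
(the arc-length derivative of the unit tangent) and ``z_i`` the dual
edge length.  Barbed filament ends that cross the polygon within a
short "overgrowth" reach become attached to a freshly inserted vertex;
the attachment behaves as one more separation-potential bond, which is
how propulsive and Newtonian reaction forces are exchanged, and gates
further polymerization through the Brownian-ratchet factor
``exp(-f * delta / kT)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon


@dataclasses.dataclass
class Attachment:
    id: int
    end_id: int          # actin end node
    vertex_id: int       # membrane vertex
    rest_length: float   # bond rest length, internal units
    created: float       # simulation time of creation


class MembranePolygon:
    """Ordered CCW cycle of movable vertices with stable integer ids."""

    def __init__(self, positions: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 2 or len(positions) < 5:
            raise ValueError("membrane needs >= 5 vertices of shape (n, 2)")
        self.order: list[int] = list(range(len(positions)))
        self.pos: dict[int, np.ndarray] = {
            i: positions[i].copy() for i in self.order}
        self._next_id = len(positions)
        self._shape_cache: Optional[Polygon] = None
        self._coords_cache: Optional[np.ndarray] = None
        if self.signed_area() < 0:
            raise ValueError("vertices must wind counterclockwise")

    # -- bookkeeping --------------------------------------------------
    def __len__(self) -> int:
        return len(self.order)

    def coords(self) -> np.ndarray:
        if self._coords_cache is None:
            self._coords_cache = np.array([self.pos[i] for i in self.order])
        return self._coords_cache

    def index_of(self, vid: int) -> int:
        return self.order.index(vid)

    def _invalidate(self) -> None:
        self._shape_cache = None
        self._coords_cache = None

    def inscribed_radius(self, center: np.ndarray) -> float:
        """Distance from ``center`` to the nearest boundary point; the
        open disk of this radius around an interior center is inside."""
        c = self.coords()
        a = c
        b = np.roll(c, -1, axis=0)
        ab = b - a
        ap = center[None, :] - a
        t = np.clip(np.einsum("ij,ij->i", ap, ab)
                    / np.einsum("ij,ij->i", ab, ab), 0.0, 1.0)
        closest = a + t[:, None] * ab
        return float(np.min(np.linalg.norm(closest - center[None, :],
                                           axis=1)))

    def shape(self) -> Polygon:
        if self._shape_cache is None:
            self._shape_cache = Polygon(self.coords())
        return self._shape_cache

    def move_vertex(self, vid: int, new_pos: np.ndarray) -> None:
        self.pos[vid] = np.asarray(new_pos, dtype=float).copy()
        self._invalidate()

    def insert_vertex(self, edge_start_index: int, point: np.ndarray) -> int:
        """Insert a vertex on the edge (i, i+1); returns its id."""
        vid = self._next_id
        self._next_id += 1
        self.pos[vid] = np.asarray(point, dtype=float).copy()
        self.order.insert(edge_start_index + 1, vid)
        self._invalidate()
        return vid

    # -- geometry -----------------------------------------------------
    def signed_area(self) -> float:
        c = self.coords()
        x, y = c[:, 0], c[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        c = self.coords()
        return float(np.sum(np.linalg.norm(np.roll(c, -1, axis=0) - c, axis=1)))

    def is_simple(self) -> bool:
        return LinearRing(self.coords()).is_simple

    def contains(self, point: np.ndarray, tolerance: float = 0.0) -> bool:
        p = Point(point)
        shape = self.shape()
        if shape.covers(p):
            return True
        return tolerance > 0 and shape.exterior.distance(p) <= tolerance

    # -- discrete mean curvature --------------------------------------
    def _local(self, idx: int) -> tuple[np.ndarray, ...]:
        n = len(self.order)
        return tuple(self.pos[self.order[(idx + k) % n]] for k in (-2, -1, 0, 1, 2))

    def mean_curvature_at_index(self, idx: int) -> float:
        """|dT/dw| at the vertex: ||(T_{i+1} - T_i)|| / z_i."""
        _, xm1, x0, xp1, _ = self._local(idx)
        v_i = float(np.linalg.norm(x0 - xm1))
        v_ip1 = float(np.linalg.norm(xp1 - x0))
        t_i = (x0 - xm1) / v_i
        t_ip1 = (xp1 - x0) / v_ip1
        z_i = 0.5 * (v_i + v_ip1)
        return float(np.linalg.norm(t_ip1 - t_i)) / z_i

    def mean_curvatures(self) -> np.ndarray:
        return np.array([self.mean_curvature_at_index(i)
                         for i in range(len(self.order))])


def helfrich_energy(poly: MembranePolygon, kappa: float,
                    area_coeff: float = 0.0,
                    length_coeff: float = 0.0) -> float:
    """Discrete membrane energy 2*kappa*sum H_i^2 z_i (+ optional terms)."""
    c = poly.coords()
    n = len(c)
    e = c - np.roll(c, 1, axis=0)            # edge i: x_i - x_{i-1}
    v = np.linalg.norm(e, axis=1)            # v_i
    t = e / v[:, None]                       # T_i
    u = np.roll(t, -1, axis=0) - t           # u_i = T_{i+1} - T_i
    z = 0.5 * (v + np.roll(v, -1))           # z_i
    energy = 2.0 * kappa * float(np.sum(np.sum(u * u, axis=1) / z))
    if area_coeff:
        energy += area_coeff * poly.signed_area()
    if length_coeff:
        energy += length_coeff * float(np.sum(v))
    return energy


def helfrich_gradient(poly: MembranePolygon, idx: int, kappa: float,
                      area_coeff: float = 0.0,
                      length_coeff: float = 0.0) -> np.ndarray:
    """Analytic d U_mem / d x_j for the vertex at polygon index ``idx``.

    Only the three curvature summands containing x_j contribute.  With
    T_i the unit tangent of edge i and P_i = (I - T_i T_i^T)/v_i:

        dE/dx_j = 2k * [ (2/z_{j-1}) P_j u_{j-1}
                       - (|u_{j-1}|^2 / z_{j-1}^2) T_j / 2
                       + (2/z_j)(-P_{j+1} - P_j) u_j
                       - (|u_j|^2 / z_j^2)(T_j - T_{j+1}) / 2
                       + (2/z_{j+1}) P_{j+1} u_{j+1}
                       + (|u_{j+1}|^2 / z_{j+1}^2) T_{j+1} / 2 ]
    """
    n = len(poly.order)
    x = lambda k: poly.pos[poly.order[(idx + k) % n]]
    xm2, xm1, x0, xp1, xp2 = (x(k) for k in (-2, -1, 0, 1, 2))

    def edge(a, b):
        d = b - a
        v = float(np.linalg.norm(d))
        return d / v, v

    t_jm1, v_jm1 = edge(xm2, xm1)     # T_{j-1}
    t_j, v_j = edge(xm1, x0)          # T_j
    t_jp1, v_jp1 = edge(x0, xp1)      # T_{j+1}
    t_jp2, v_jp2 = edge(xp1, xp2)     # T_{j+2}

    u_jm1 = t_j - t_jm1
    u_j = t_jp1 - t_j
    u_jp1 = t_jp2 - t_jp1
    z_jm1 = 0.5 * (v_jm1 + v_j)
    z_j = 0.5 * (v_j + v_jp1)
    z_jp1 = 0.5 * (v_jp1 + v_jp2)

    def proj(t, v):
        return (np.eye(2) - np.outer(t, t)) / v

    p_j = proj(t_j, v_j)
    p_jp1 = proj(t_jp1, v_jp1)

    g = (2.0 / z_jm1) * (p_j @ u_jm1)
    g -= (np.dot(u_jm1, u_jm1) / z_jm1 ** 2) * t_j / 2.0
    g += (2.0 / z_j) * ((-p_jp1 - p_j) @ u_j)
    g -= (np.dot(u_j, u_j) / z_j ** 2) * (t_j - t_jp1) / 2.0
    g += (2.0 / z_jp1) * (p_jp1 @ u_jp1)
    g += (np.dot(u_jp1, u_jp1) / z_jp1 ** 2) * t_jp1 / 2.0
    g *= 2.0 * kappa

    if area_coeff:
        g += area_coeff * 0.5 * np.array([xp1[1] - xm1[1], xm1[0] - xp1[0]])
    if length_coeff:
        g += length_coeff * (t_j - t_jp1)
    return g


# ---------------------------------------------------------------------
# actin-membrane coupling
# ---------------------------------------------------------------------

def segment_edge_intersection(p0: np.ndarray, p1: np.ndarray,
                              q0: np.ndarray, q1: np.ndarray
                              ) -> Optional[np.ndarray]:
    """Intersection point of segments [p0,p1] and [q0,q1], or None."""
    d1 = p1 - p0
    d2 = q1 - q0
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-14:
        return None
    dp = q0 - p0
    t = (dp[0] * d2[1] - dp[1] * d2[0]) / denom
    s = (dp[0] * d1[1] - dp[1] * d1[0]) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= s <= 1.0:
        return p0 + t * d1
    return None


def find_crossing(poly: MembranePolygon, p0: np.ndarray, p1: np.ndarray
                  ) -> Optional[tuple[int, np.ndarray]]:
    """First membrane edge crossed by [p0, p1] -> (edge start index, point).

    Vectorized over all polygon edges; "first" means nearest to p0.
    """
    c = poly.coords()
    q0 = c
    q1 = np.roll(c, -1, axis=0)
    d1 = p1 - p0
    d2 = q1 - q0
    denom = d1[0] * d2[:, 1] - d1[1] * d2[:, 0]
    ok = np.abs(denom) > 1e-14
    if not np.any(ok):
        return None
    dp = q0 - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dp[:, 0] * d2[:, 1] - dp[:, 1] * d2[:, 0]) / denom
        s = (dp[:, 0] * d1[1] - dp[:, 1] * d1[0]) / denom
    hit = ok & (t >= 0.0) & (t <= 1.0) & (s >= 0.0) & (s <= 1.0)
    if not np.any(hit):
        return None
    idxs = np.nonzero(hit)[0]
    i = int(idxs[np.argmin(t[idxs])])
    return i, p0 + t[i] * d1


def find_crossings_batch(poly: MembranePolygon, p0s: np.ndarray,
                         p1s: np.ndarray
                         ) -> list[Optional[tuple[int, np.ndarray]]]:
    """Nearest-edge crossing for many probe segments at once.

    Returns, per probe [p0s[k], p1s[k]], either (edge start index,
    intersection point) or None, identical to :func:`find_crossing`.
    """
    c = poly.coords()
    q0 = c
    d2 = np.roll(c, -1, axis=0) - c                 # (E, 2)
    d1 = p1s - p0s                                  # (K, 2)
    denom = d1[:, None, 0] * d2[None, :, 1] - d1[:, None, 1] * d2[None, :, 0]
    dp = q0[None, :, :] - p0s[:, None, :]           # (K, E, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dp[:, :, 0] * d2[None, :, 1]
             - dp[:, :, 1] * d2[None, :, 0]) / denom
        s = (dp[:, :, 0] * d1[:, None, 1]
             - dp[:, :, 1] * d1[:, None, 0]) / denom
    hit = ((np.abs(denom) > 1e-14) & (t >= 0.0) & (t <= 1.0)
           & (s >= 0.0) & (s <= 1.0))
    out: list[Optional[tuple[int, np.ndarray]]] = []
    t_masked = np.where(hit, t, np.inf)
    best = np.argmin(t_masked, axis=1)
    for k in range(len(p0s)):
        i = int(best[k])
        if not np.isfinite(t_masked[k, i]):
            out.append(None)
        else:
            out.append((i, p0s[k] + t[k, i] * d1[k]))
    return out


def ratchet_factor(load: float, delta: float) -> float:
    """Brownian-ratchet elongation multiplier exp(-f*delta/kT).

    ``load`` is the compressive force (kT/unit, >= 0) resisting insertion
    and ``delta`` the insertion length (units); energies are in kT so no
    explicit temperature factor appears.
    """
    if load <= 0.0:
        return 1.0
    return math.exp(-load * delta)


def make_circle(radius: float, n_vertices: int,
                center: tuple[float, float] = (0.0, 0.0)) -> MembranePolygon:
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(ang),
                           center[1] + radius * np.sin(ang)])
    return MembranePolygon(pts)


def make_ellipse(a: float, b: float, n_vertices: int) -> MembranePolygon:
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([a * np.cos(ang), b * np.sin(ang)])
    return MembranePolygon(pts)
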