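"""Energy-based biophysics: clipped Lennard-Jones separation potential,
radial gradients and Hessians, and the angle-bending terms.

Everything here is a pure function of positions and
:class:`~spinedgg.params.Params`-derived constants, in internal units
(length = coarse-grained resting length, energy = kT).  The stochastic
kinetic and thermal rules that consume these quantities live in
:mod:`spinedgg.kinetics`.

Separation (radial) sector
--------------------------
The bond between two connected objects carries the 12-6 potential

    U(r) = eps * [ (sigma/r)^12 - (sigma/r)^6 ],

with ``sigma`` chosen so the zero-force separation ``r_min = 2^{1/6}
sigma`` equals the bond's rest length.  Below the clip point
``eps_clip * r_min`` the potential continues linearly with matched value
and slope, which bounds the repulsive-core force and keeps the
overdamped update well conditioned.

Bending sector
--------------
Three consecutive objects x1, x2, x3 carry

    U_ang = (kB/2) * (acos(a) - theta_target)^2,
    a = cos(theta) = (x2-x1).(x3-x2) / (|x2-x1| |x3-x2|),

whose gradient is expressed through the K-vectors below.  The
``a -> 1`` limit with a straight target angle is nonsingular (l'Hopital)
and is evaluated explicitly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np


@dataclasses.dataclass(frozen=True)
class Bond:
    """A clipped-LJ bond with well depth ``eps`` (kT) and rest length."""

    eps: float
    rest_length: float = 1.0
    eps_clip: float = 0.75

    @property
    def sigma(self) -> float:
        return self.rest_length * 2.0 ** (-1.0 / 6.0)

    @property
    def clip_r(self) -> float:
        return self.eps_clip * self.rest_length

    # -- unclipped ----------------------------------------------------
    def u_raw(self, r: float) -> float:
        s6 = (self.sigma / r) ** 6
        return self.eps * (s6 * s6 - s6)

    def du_raw(self, r: float) -> float:
        s6 = (self.sigma / r) ** 6
        return self.eps * (-12.0 * s6 * s6 + 6.0 * s6) / r

    def d2u_raw(self, r: float) -> float:
        s6 = (self.sigma / r) ** 6
        return self.eps * (156.0 * s6 * s6 - 42.0 * s6) / r ** 2

    # -- clipped ------------------------------------------------------
    def u(self, r: float) -> float:
        """Clipped potential: linear continuation below the clip point."""
        if r >= self.clip_r:
            return self.u_raw(r)
        return self.u_raw(self.clip_r) + self.du_raw(self.clip_r) * (r - self.clip_r)

    def du(self, r: float) -> float:
        if r >= self.clip_r:
            return self.du_raw(r)
        return self.du_raw(self.clip_r)

    def d2u(self, r: float) -> float:
        if r >= self.clip_r:
            return self.d2u_raw(r)
        return 0.0

    def psi(self, r: float) -> float:
        """psi(r) = U'(r)/r, the per-edge radial force coefficient."""
        return self.du(r) / r


class Edge(NamedTuple):
    """A separation-potential edge seen from a central node."""

    xj: np.ndarray
    bond: Bond


def radial_energy(xl: np.ndarray, edges: list[Edge]) -> float:
    return sum(e.bond.u(float(np.linalg.norm(xl - e.xj))) for e in edges)


def radial_gradient(xl: np.ndarray, edges: list[Edge]) -> np.ndarray:
    """Gradient of the summed separation energy at the central node.

    grad = sum_j psi(|xl - xj|) (xl - xj); bundle links and membrane
    attachments enter as extra edges with their own bonds.
    """
    g = np.zeros(2)
    for e in edges:
        d = xl - e.xj
        r = float(np.linalg.norm(d))
        g += e.bond.psi(r) * d
    return g


def radial_hessian_block(xl: np.ndarray, edges: list[Edge]) -> np.ndarray:
    """Exact 2x2 second-derivative block of the separation energy."""
    h = np.zeros((2, 2))
    for e in edges:
        d = xl - e.xj
        r = float(np.linalg.norm(d))
        n = d / r
        nn = np.outer(n, n)
        h += e.bond.d2u(r) * nn + e.bond.psi(r) * (np.eye(2) - nn)
    return h

def radial_hessian_diag(xl: np.ndarray, edges: list[Edge],
                        eps_sep: float = 0.0) -> np.ndarray:
    """Weighted-graph-Laplacian diagonal block: (sum_j U'' + eps^2) * I.

    This is the isotropic curvature scale used as the precision of the
    thermal proposal: the along-bond (longitudinal) component of
    :func:`radial_hessian_block`, applied isotropically.  At rest
    separation the block's transverse component U'(r)/r vanishes, so
    the scalar is the block's only nonzero curvature there.
    """
    scale = sum(e.bond.d2u(float(np.linalg.norm(xl - e.xj))) for e in edges)
    return (scale + eps_sep ** 2) * np.eye(2)


# ---------------------------------------------------------------------
# angle-bending sector
# ---------------------------------------------------------------------

class AngleTerms(NamedTuple):
    a: float          # cos(theta)
    b: float          # |x3-x2| / |x2-x1|
    c: float          # |x2-x1| * |x3-x2|
    L: np.ndarray     # x1 - 2 x2 + x3
    Lt: np.ndarray    # b x1 - (b + 1/b) x2 + x3 / b
    K: np.ndarray     # K_123 = (x2-x3) - a b (x1-x2)
    Kt: np.ndarray    # K_321 = (x2-x1) - (a/b)(x3-x2)


def angle_terms(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray) -> AngleTerms:
    """The scalar and vector building blocks of the bending gradient.

    With u = x2-x1, v = x3-x2: a = cos(theta), b = |v|/|u|, c = |u||v|;
    the K-vectors satisfy K_123 + K_321 = -(L + a*Lt) and the index
    reversal K~_ijk = K_kji (with b -> 1/b under reversal), which is
    what makes the three per-node gradients of one triple sum to zero.
    """
    u = x2 - x1
    v = x3 - x2
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate geometry: coincident points")
    a = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    b = nv / nu
    c = nu * nv
    L = x1 - 2.0 * x2 + x3
    Lt = b * x1 - (b + 1.0 / b) * x2 + x3 / b
    K = (x2 - x3) - a * b * (x1 - x2)
    Kt = (x2 - x1) - (a / b) * (x3 - x2)
    return AngleTerms(a, b, c, L, Lt, K, Kt)


def bend_angle(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray) -> float:
    """Signed middle angle theta at x2 (zero when colinear forward)."""
    u = x2 - x1
    v = x3 - x2
    return math.atan2(float(u[0] * v[1] - u[1] * v[0]), float(np.dot(u, v)))


def angle_energy(x1, x2, x3, theta_target: float, k_bend: float) -> float:
    t = angle_terms(x1, x2, x3)
    return 0.5 * k_bend * (math.acos(t.a) - theta_target) ** 2


def _angle_prefactor(a: float, theta_target: float) -> float:
    """(acos(a) - theta_target) / sqrt(1 - a^2), with its a->1 limit.

    For theta_target = 0 the ratio tends to 1 as a -> 1 (l'Hopital); for
    a -> -1 the angle tends to pi and the ratio diverges like the true
    gradient of a fully folded triple, so we cap via a floor on 1-a^2.
    """
    s2 = 1.0 - a * a
    if s2 < 1e-14:
        if a > 0 and theta_target == 0.0:
            return 1.0
        s2 = 1e-14
    return (math.acos(a) - theta_target) / math.sqrt(s2)


def angle_gradient_interior(x1, x2, x3, theta_target: float,
                            k_bend: float) -> np.ndarray:
    """d U_ang / d x2 = -kB * f/c * (L + a*Lt) = +kB * f/c * (K + Kt)."""
    t = angle_terms(x1, x2, x3)
    f = _angle_prefactor(t.a, theta_target)
    return -(k_bend * f / t.c) * (t.L + t.a * t.Lt)


def angle_gradient_end(x1, x2, x3, theta_target: float, k_bend: float,
                       which: str = "first") -> np.ndarray:
    """Gradient at an end node of the triple (x1 if ``which='first'``)."""
    if which == "first":
        t = angle_terms(x1, x2, x3)
        k = t.K
    elif which == "last":
        t = angle_terms(x3, x2, x1)   # K_321 of the forward triple
        k = t.K
    else:
        raise ValueError("which must be 'first' or 'last'")
    f = _angle_prefactor(t.a, theta_target)
    return -(k_bend * f / t.c) * k


def angle_hessian_outer(x1, x2, x3, k_bend: float) -> np.ndarray:
    """Rank-one PSD part of the interior bending Hessian,
    kB/(c^2 (1-a^2)) * (K+Kt) (K+Kt)^T.

    Exact (equal to the full second derivative) when the enclosed angle
    sits at the target angle, where the dropped variable-sign term
    proportional to (acos a - theta_target) vanishes.
    """
    t = angle_terms(x1, x2, x3)
    s2 = max(1.0 - t.a * t.a, 1e-14)
    w = t.K + t.Kt
    return (k_bend / (t.c ** 2 * s2)) * np.outer(w, w)


def angle_hessian_diag(x1, x2, x3, k_bend: float,
                       eps_ang: float = 0.0) -> np.ndarray:
    """Positive-definite isotropic bending Hessian for thermal proposals:
    the positive eigenvalue (= Frobenius norm of the rank-one part) times
    the identity, plus the eps_ang^2 regularizer."""
    h = angle_hessian_outer(x1, x2, x3, k_bend)
    lam = float(np.trace(h))   # rank-one: trace = positive eigenvalue
    return (lam + eps_ang ** 2) * np.eye(2)
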