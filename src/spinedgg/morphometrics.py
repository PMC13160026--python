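"""Membrane phenotype measurement and sweep statistics.

A simulation snapshot is summarized by three membrane phenotypes --
enclosed area, perimeter, and aspect ratio (the principal-axis ratio of
the polygon's gyration tensor).  Synthesis-rate sweeps rerun the
simulator over a log-spaced multiplier grid centered on the basal rate
and summarize each phenotype's dose dependence with Pearson's r and a
one-sided Jonckheere-Terpstra trend test whose direction is set by the
sign of r.  Double sweeps step one species by eta per grid point and a
second species by 1/eta^q, the change of variables used to probe
epistatic masking between actin-binding proteins.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .membrane import MembranePolygon
from .params import Params, default_params
from .pools import apply_sweep_multiplier, dissociation_constant  # noqa: F401
from . import engine
from . import fixtures

PHENOTYPES = ("area", "perimeter", "aspect_ratio")


@dataclasses.dataclass
class MorphometricsRecord:
    time: float            # s
    area: float            # um^2 (or unit^2 if unit_length_um = 1)
    perimeter: float       # um
    aspect_ratio: float    # dimensionless, >= 1


def gyration_tensor(poly: MembranePolygon) -> np.ndarray:
    """Second central moment (per unit area) of the polygon interior."""
    c = poly.coords()
    x, y = c[:, 0], c[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    ixx = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    iyy = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    ixy = float(np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y)
                       * cross)) / 24.0
    cov = np.array([[iyy / area - cx * cx, ixy / area - cx * cy],
                    [ixy / area - cx * cy, ixx / area - cy * cy]])
    return cov


def measure(poly: MembranePolygon, unit_length_um: float = 1.0,
            time: float = 0.0,
            aspect_method: str = "gyration") -> MorphometricsRecord:
    """Area (shoelace), perimeter, and aspect ratio.

    ``aspect_method``: "gyration" (principal-axis ratio of the second
    central moment tensor, rotation invariant; default) or "bbox"
    (axis-aligned bounding-box side ratio).
    """
    if aspect_method == "gyration":
        lam = np.linalg.eigvalsh(gyration_tensor(poly))
        aspect = math.sqrt(max(lam) / max(min(lam), 1e-300))
    elif aspect_method == "bbox":
        c = poly.coords()
        spans = np.ptp(c, axis=0)
        aspect = float(max(spans) / max(min(spans), 1e-300))
    else:
        raise ValueError("aspect_method must be 'gyration' or 'bbox'")
    return MorphometricsRecord(
        time=time,
        area=poly.signed_area() * unit_length_um ** 2,
        perimeter=poly.perimeter() * unit_length_um,
        aspect_ratio=aspect,
    )


def measure_state(state: engine.SimState) -> MorphometricsRecord:
    unit_um = state.params.l0 * 1e6
    return measure(state.membrane, unit_length_um=unit_um, time=state.time)


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-based p-value.

    A constant input has no defined correlation; (0.0, 1.0) is returned
    so a dose-insensitive phenotype reads as "no trend".
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return 0.0, 1.0
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------

def jt_statistic(groups: Sequence[Sequence[float]]) -> float:
    """J = sum over ordered group pairs of #(a < b) + 0.5 #(a == b)."""
    j = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        for a in gi:
            for b in gj:
                if a < b:
                    j += 1.0
                elif a == b:
                    j += 0.5
    return j


def _jt_exact_tail(groups: list[np.ndarray], observed: float,
                   alternative: str) -> float:
    """Exact permutation tail P(J >=/<= observed) by enumerating every
    distinct assignment of the pooled observations to the group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def rec(remaining: tuple[float, ...], k: int):
        # index combinations enumerate each equally likely split exactly
        # once, so tied values carry their correct multiplicities
        if k == len(sizes) - 1:
            yield [list(remaining)]
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[k]):
            chosen = [remaining[i] for i in combo]
            combo_set = set(combo)
            rest = tuple(v for i, v in enumerate(remaining)
                         if i not in combo_set)
            for tail in rec(rest, k + 1):
                yield [chosen] + tail

    count = total = 0
    for assignment in rec(tuple(pooled), 0):
        j = jt_statistic(assignment)
        total += 1
        if alternative == "increasing":
            count += j >= observed - 1e-9
        else:
            count += j <= observed + 1e-9
    return count / total


def jonckheere_terpstra(groups: Sequence[Sequence[float]],
                        alternative: str = "increasing"
                        ) -> tuple[float, float]:
    """One-sided Jonckheere-Terpstra trend test across dose-ordered
    groups.

    Returns (J, p).  ``alternative`` is "increasing" or "decreasing";
    callers following the sweep convention pick the side from the sign
    of the accompanying Pearson r.  For 10 or fewer observations the
    p-value is the exact permutation tail; above that the normal
    approximation with tie-corrected variance is used.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    j = jt_statistic(groups)
    pooled_all = np.concatenate(groups)
    if np.all(pooled_all == pooled_all[0]):
        return j, 0.5   # degenerate: J has no distribution (z = 0)
    if len(pooled_all) <= 10:
        return j, _jt_exact_tail(groups, j, alternative)
    ns = np.array([len(g) for g in groups], dtype=float)
    n = float(ns.sum())
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (n * n - float(np.sum(ns ** 2))) / 4.0
    v1 = (n * (n - 1) * (2 * n + 5)
          - float(np.sum(ns * (ns - 1) * (2 * ns + 5)))
          - float(np.sum(t * (t - 1) * (2 * t + 5)))) / 72.0
    v2 = (float(np.sum(ns * (ns - 1) * (ns - 2)))
          * float(np.sum(t * (t - 1) * (t - 2)))
          / (36.0 * n * (n - 1) * (n - 2)))
    v3 = (float(np.sum(ns * (ns - 1))) * float(np.sum(t * (t - 1)))
          / (8.0 * n * (n - 1)))
    var = v1 + v2 + v3
    if var <= 0.0:
        return j, 0.5
    z = (j - mean) / math.sqrt(var)
    if alternative == "increasing":
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.norm.cdf(z))
    return j, p


# ---------------------------------------------------------------------
# epistasis change of variables
# ---------------------------------------------------------------------

def epistasis_q(r_a: float, r_b: float) -> float:
    """Exponent q from the slope ratio of two single sweeps:
    d(phenotype)/d(alpha) / d(phenotype)/d(gamma) ~ -q."""
    return -r_a / r_b


def change_of_variables(alpha: float, gamma: float, q: float
                        ) -> tuple[float, float]:
    """(alpha, gamma) -> (mu, nu) with mu = alpha + gamma/q,
    nu = alpha - gamma/q."""
    return alpha + gamma / q, alpha - gamma / q


def invert_change_of_variables(mu: float, nu: float, q: float
                               ) -> tuple[float, float]:
    """alpha = (mu + nu)/2, gamma = (q/2)(mu - nu)."""
    return (mu + nu) / 2.0, (q / 2.0) * (mu - nu)


# ---------------------------------------------------------------------
# sweep driver
# ---------------------------------------------------------------------

@dataclasses.dataclass
class SweepDesign:
    """A single or double synthesis-rate parameter sweep.

    The grid is log-spaced with ``n_steps`` points (odd, midpoint = the
    unmodified basal rate) spanning ``span`` decades on each side for
    ``species_a``; a double sweep concomitantly applies the reciprocal
    multiplier raised to ``q`` to ``species_b``.
    """

    species_a: str
    species_b: Optional[str] = None
    q: float = 1.0
    n_steps: int = 7
    span: float = 1.0              # decades each side (0.1x .. 10x)
    upper_span: Optional[float] = None   # truncated upper end if not None
    replicates: int = 5
    t_measure: float = 20.0        # s
    seed_base: int = 0
    stimulated: bool = True
    include_influx: bool = False
    max_events: Optional[int] = None
    #: reuse one seed per replicate across all grid points (common random
    #: numbers): pairs the dose arms for variance reduction in short runs
    paired_seeds: bool = False

    def exponents(self) -> np.ndarray:
        if self.n_steps < 3 or self.n_steps % 2 == 0:
            raise ValueError("n_steps must be odd and >= 3")
        m = self.n_steps // 2
        lo = np.linspace(-self.span, 0.0, m + 1)[:-1]
        hi_span = self.span if self.upper_span is None else self.upper_span
        hi = np.linspace(0.0, hi_span, m + 1)[1:]
        return np.concatenate([lo, [0.0], hi])


def _sweep_params(base: Params, design: SweepDesign, expo: float) -> Params:
    p = apply_sweep_multiplier(base, design.species_a, 10.0 ** expo,
                               include_influx=design.include_influx)
    if design.species_b is not None:
        p = apply_sweep_multiplier(p, design.species_b,
                                   10.0 ** (-design.q * expo),
                                   include_influx=design.include_influx)
    return p


def run_sweep(design: SweepDesign, params: Optional[Params] = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sweep and summarize it.

    Returns ``(records, summary)``: tidy per-replicate phenotype records
    and, per phenotype, Pearson's r/p against the dose exponent plus the
    one-sided Jonckheere-Terpstra p with the side picked by sign(r).
    """
    base = params or default_params()
    rows = []
    expos = design.exponents()
    for step, expo in enumerate(expos):
        p = _sweep_params(base, design, float(expo))
        for rep in range(design.replicates):
            seed = (design.seed_base + rep if design.paired_seeds
                    else design.seed_base + 1009 * step + rep)
            state = fixtures.seed_spine(p, seed=seed,
                                        stimulated=design.stimulated)
            engine.run(state, design.t_measure,
                       max_events=design.max_events)
            rec = measure_state(state)
            rows.append({
                "species": design.species_a,
                "species_b": design.species_b or "",
                "q": design.q,
                "step": step,
                "exponent": float(expo),
                "multiplier": 10.0 ** float(expo),
                "replicate": rep,
                "time": rec.time,
                "area": rec.area,
                "perimeter": rec.perimeter,
                "aspect_ratio": rec.aspect_ratio,
            })
    records = pd.DataFrame(rows)
    summary = summarize_sweep(records)
    return records, summary


def summarize_sweep(records: pd.DataFrame) -> pd.DataFrame:
    out = []
    for phen in PHENOTYPES:
        r, p_r = pearson_r(records["exponent"], records[phen])
        groups = [grp[phen].to_numpy()
                  for _, grp in records.groupby("step", sort=True)]
        side = "increasing" if r >= 0 else "decreasing"
        j, p_jt = jonckheere_terpstra(groups, alternative=side)
        out.append({"phenotype": phen, "pearson_r": r, "pearson_p": p_r,
                    "jt_J": j, "jt_p": p_jt, "side": side})
    return pd.DataFrame(out)
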