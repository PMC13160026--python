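"""Well-mixed free-protein pools.

Each species M (free actin monomers, Arp2/3, cofilin, Aip1,
CaMKII-beta, capping protein) follows the linear ODE

    dM/dt = I_S,M + I_M - k_M * M

with basal synthesis ``I_M``, stimulated influx ``I_S,M`` (active only
in "LTP mode"; negative for CaMKII-beta) and first-order degradation
``k_M``.  Amounts are continuous molecule counts; rate constants are
given in molar units and converted with the effective volume
``V = membrane area * slab thickness``, so propensities scale with the
instantaneous spine size.  The ODE is advanced by its closed-form
solution between stochastic events, which keeps amounts nonnegative for
any time step.
"""

from __future__ import annotations

import dataclasses
import math

from .params import AVOGADRO, Params

SPECIES = ("actin", "arp23", "cof", "aip1", "camkii", "cap")


@dataclasses.dataclass
class SpeciesPools:
    params: Params
    counts: dict[str, float]
    stimulated: bool = False

    # -- conversions --------------------------------------------------
    def concentration(self, species: str, area_units2: float) -> float:
        """Molar concentration of the free pool at the given area."""
        vol = self.params.volume_liters(area_units2)
        return self.counts[species] / (AVOGADRO * vol)

    def propensity_factor(self, k_on: float, species: str,
                          area_units2: float) -> float:
        """Convert a per-molar on rate into a per-second propensity,
        k_on * N_free / (N_A * V_eff)."""
        return k_on * self.concentration(species, area_units2)

    # -- dynamics -----------------------------------------------------
    def _rates(self, species: str, area_units2: float) -> tuple[float, float]:
        """(production in counts/s, degradation in 1/s)."""
        p = self.params
        synth = p.raw[f"k_synth_{species}"]
        if self.stimulated:
            synth += p.raw[f"k_influx_{species}"]
        vol = p.volume_liters(area_units2)
        return synth * AVOGADRO * vol, p.raw[f"k_deg_{species}"]

    def ode_advance(self, dt: float, area_units2: float) -> None:
        """Advance every pool by the closed-form solution over dt.

        M(t+dt) = M_ss + (M - M_ss) * exp(-k dt) with M_ss = I_tot/k;
        clamped at zero in case a negative influx drives M_ss < 0.
        """
        if dt <= 0.0:
            return
        for species in SPECIES:
            prod, k = self._rates(species, area_units2)
            m = self.counts[species]
            if k > 0.0:
                m_ss = prod / k
                m = m_ss + (m - m_ss) * math.exp(-k * dt)
            else:
                m = m + prod * dt
            self.counts[species] = max(m, 0.0)

    def take(self, species: str, amount: float) -> None:
        self.counts[species] = max(self.counts[species] - amount, 0.0)

    def give(self, species: str, amount: float) -> None:
        self.counts[species] += amount


def steady_state_concentration(params: Params, species: str,
                               stimulated: bool = False) -> float:
    """Fixed point I/k of the pool ODE, in molar."""
    synth = params.raw[f"k_synth_{species}"]
    if stimulated:
        synth += params.raw[f"k_influx_{species}"]
    deg = params.raw[f"k_deg_{species}"]
    if deg <= 0.0:
        return 0.0   # no fixed point without degradation
    return max(synth / deg, 0.0)


def init_steady_state(params: Params, area_units2: float,
                      stimulated: bool = False) -> SpeciesPools:
    """Pools initialized at the basal steady state I_M/k_M (as counts).

    Initialization always uses the basal rates; ``stimulated`` only
    switches the influx terms on for the subsequent dynamics.
    """
    vol = params.volume_liters(area_units2)
    counts = {s: steady_state_concentration(params, s) * AVOGADRO * vol
              for s in SPECIES}
    return SpeciesPools(params=params, counts=counts, stimulated=stimulated)


def apply_sweep_multiplier(params: Params, species: str, factor: float,
                           include_influx: bool = False) -> Params:
    """Scale a species' basal synthesis rate (and optionally its influx)."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    updates = {f"k_synth_{species}": params.raw[f"k_synth_{species}"] * factor}
    if include_influx:
        updates[f"k_influx_{species}"] = (
            params.raw[f"k_influx_{species}"] * factor)
    return params.with_updates(**updates)


def dissociation_constant(k_off: float, k_on: float) -> float:
    """K_d = k_off / k_on, in molar (k_off 1/s, k_on 1/(M s))."""
    return k_off / k_on
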