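"""Freshwater carbonate system: Gran alkalinity and DIC from pH/T/TA.

Total alkalinity (TA) is obtained from an acidimetric Gran titration:
past the carbonic-acid equivalence point the Gran function
``F(Va) = (V0 + Va) * 10**(-pH)`` is linear in the added acid volume and
its x-intercept is the equivalence volume.  Dissolved inorganic carbon
(DIC = CO2* + HCO3- + CO3^2-) then follows from TA, pH and temperature
through the carbonic-acid dissociation constants.

Constants are zero-ionic-strength freshwater formulations: K1 and K2
from the Plummer & Busenberg temperature fits, Kw from the Harned & Owen
fit, all on the mol/L (molar) scale.  Ionic-strength corrections are
deliberately omitted — they are negligible for a dilute oligotrophic
lake.  pH is treated as free-proton scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

GRAN_PH_CUTOFF = 4.5


@dataclass(frozen=True)
class GranTitration:
    """An acidimetric titration point series for one sample."""

    sample_volume: float  # V0, L
    acid_concentration: float  # Ca, mol/L
    acid_volumes: np.ndarray  # Va, L, strictly increasing
    ph: np.ndarray

    def __post_init__(self) -> None:
        va = np.asarray(self.acid_volumes, float)
        if np.any(np.diff(va) <= 0):
            raise ValueError("acid volumes must be strictly increasing")
        if len(va) != len(self.ph):
            raise ValueError("acid_volumes and ph must have equal length")


@dataclass(frozen=True)
class GranResult:
    ta: float  # mol/L
    equivalence_volume: float  # L
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CarbonateSystem:
    temperature: float  # degC
    ph: float
    ta: float  # mol/L
    k1: float
    k2: float
    kw: float
    dic: float  # mol/L
    co2: float
    hco3: float
    co3: float


def equilibrium_constants(temperature: float) -> tuple[float, float, float]:
    """(K1, K2, Kw) at ``temperature`` degC, zero ionic strength, mol/L.

    Raises for temperatures outside 0-40 degC, the validity range relevant
    to temperate surface waters.
    """
    if not 0.0 <= temperature <= 40.0:
        raise ValueError(f"temperature {temperature} degC outside 0-40 range")
    tk = temperature + 273.15
    log_k1 = (
        -356.3094
        - 0.06091964 * tk
        + 21834.37 / tk
        + 126.8339 * np.log10(tk)
        - 1684915.0 / tk**2
    )
    log_k2 = (
        -107.8871
        - 0.03252849 * tk
        + 5151.79 / tk
        + 38.92561 * np.log10(tk)
        - 563713.9 / tk**2
    )
    log_kw = -4470.99 / tk + 6.0875 - 0.01706 * tk
    return 10.0**log_k1, 10.0**log_k2, 10.0**log_kw


def carbonate_alpha(h: float, k1: float, k2: float) -> tuple[float, float, float]:
    """Ionisation fractions (alpha0: CO2*, alpha1: HCO3-, alpha2: CO3^2-)."""
    denom = h * h + k1 * h + k1 * k2
    return h * h / denom, k1 * h / denom, k1 * k2 / denom


def gran_alkalinity(t: GranTitration, ph_cutoff: float = GRAN_PH_CUTOFF) -> GranResult:
    """Total alkalinity (mol/L) by Gran linearisation.

    Uses points with pH below ``ph_cutoff`` (past the carbonic-acid
    equivalence region); ordinary least squares on F(Va) gives the
    equivalence volume as the x-intercept.
    """
    va = np.asarray(t.acid_volumes, float)
    ph = np.asarray(t.ph, float)
    mask = ph < ph_cutoff
    if mask.sum() < 3:
        raise ValueError(
            f"need >=3 titration points with pH < {ph_cutoff}; got {int(mask.sum())}"
        )
    f = (t.sample_volume + va[mask]) * 10.0 ** (-ph[mask])
    fit = stats.linregress(va[mask], f)
    ve = -fit.intercept / fit.slope
    if ve <= 0:
        raise ValueError("negative equivalence volume: over-acidified or bad data")
    return GranResult(
        ta=ve * t.acid_concentration / t.sample_volume,
        equivalence_volume=ve,
        r_squared=fit.rvalue**2,
        n_points=int(mask.sum()),
    )


def dic_from_ta(temperature: float, ph: float, ta: float) -> CarbonateSystem:
    """DIC (mol/L) and speciation from temperature, pH and alkalinity.

    Carbonate alkalinity CA = TA - [OH-] + [H+]; then
    DIC = CA * (1 + h/K1 + K2/h) / (1 + 2 K2/h).
    """
    k1, k2, kw = equilibrium_constants(temperature)
    h = 10.0 ** (-ph)
    ca = ta - kw / h + h
    if ca <= 0:
        raise ValueError("alkalinity inconsistent with pH: carbonate alkalinity <= 0")
    hco3 = ca / (1.0 + 2.0 * k2 / h)
    co3 = hco3 * k2 / h
    co2 = hco3 * h / k1
    return CarbonateSystem(
        temperature=temperature,
        ph=ph,
        ta=ta,
        k1=k1,
        k2=k2,
        kw=kw,
        dic=co2 + hco3 + co3,
        co2=co2,
        hco3=hco3,
        co3=co3,
    )


def ta_from_dic(temperature: float, ph: float, dic: float) -> float:
    """Algebraic inverse of :func:`dic_from_ta` (total alkalinity, mol/L)."""
    k1, k2, kw = equilibrium_constants(temperature)
    h = 10.0 ** (-ph)
    _, a1, a2 = carbonate_alpha(h, k1, k2)
    return dic * (a1 + 2.0 * a2) + kw / h - h


def simulate_gran_titration(
    dic: float,
    sample_volume: float = 0.05,
    acid_concentration: float = 0.1,
    acid_volumes: np.ndarray | None = None,
    temperature: float = 25.0,
    sodium: float | None = None,
) -> GranTitration:
    """Forward-model a strong-acid titration of a NaHCO3-type solution.

    Solves the full charge balance for pH at each acid addition, assuming
    a closed system (no CO2 loss).  For a pure NaHCO3 solution the sodium
    concentration equals DIC and the alkalinity equals ``sodium`` exactly,
    so this provides an independent oracle for :func:`gran_alkalinity`.
    """
    k1, k2, kw = equilibrium_constants(temperature)
    na0 = dic if sodium is None else sodium
    if acid_volumes is None:
        # titrate well past equivalence (to pH ~3) as in field practice,
        # so the Gran region is dominated by excess strong acid
        ve = na0 * sample_volume / acid_concentration
        extra = 1e-3 * sample_volume / acid_concentration
        acid_volumes = np.linspace(0.0, 2.0 * ve + extra, 30)[1:]
    acid_volumes = np.asarray(acid_volumes, float)

    def charge_balance(ph: float, va: float) -> float:
        h = 10.0 ** (-ph)
        v = sample_volume + va
        na = na0 * sample_volume / v
        cl = acid_concentration * va / v
        ct = dic * sample_volume / v
        _, a1, a2 = carbonate_alpha(h, k1, k2)
        return na + h - cl - kw / h - ct * (a1 + 2.0 * a2)

    ph = np.array(
        [optimize.brentq(charge_balance, 0.5, 13.5, args=(va,)) for va in acid_volumes]
    )
    return GranTitration(
        sample_volume=sample_volume,
        acid_concentration=acid_concentration,
        acid_volumes=acid_volumes,
        ph=ph,
    )
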