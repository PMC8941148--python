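"""Winkler titration chemistry: dissolved O2 and bottle-incubation rates.

The Winkler method fixes dissolved O2 with Mn(II)/alkaline iodide; after
acidification the liberated iodine is titrated with thiosulfate.  The
stoichiometry is 1 mol O2 = 2 mol Mn(OH)3-oxidised = 2 mol I2 = 4 mol
S2O3^2-.  Thiosulfate itself is standardised against a KIO3 primary
standard (1 mol IO3- liberates 3 mol I2, consuming 6 mol S2O3^2-).

Respiration is the O2 drawdown between the start (T0) and end of a 24 h
dark or infrared incubation; net primary production (NPP) is the O2 gain
in bottles incubated in white light.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# mol thiosulfate consumed per mol O2 (iodometric stoichiometry)
THIOSULFATE_PER_O2 = 4.0
# mol thiosulfate per mol iodate in the KIO3 standardisation
THIOSULFATE_PER_IODATE = 6.0

#: nominal Winkler bottle capacity (L)
DEFAULT_BOTTLE_VOLUME = 115e-3
#: sample displaced by the two 1.2 mL fixing reagents (L)
DEFAULT_REAGENT_DISPLACED = 2.4e-3
#: nominal titrant concentration (mol/L)
DEFAULT_THIOSULFATE_CONC = 0.01

TREATMENTS = ("T0", "dark", "IR", "light")


@dataclass(frozen=True)
class StandardizationRecord:
    """One KIO3-standardisation titration."""

    kio3_moles: float
    titrant_volume: float  # L
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.kio3_moles <= 0:
            raise ValueError("kio3_moles must be positive")
        if self.titrant_volume <= 0:
            raise ValueError(
                f"invalid standardization record: titrant_volume="
                f"{self.titrant_volume}"
            )


@dataclass(frozen=True)
class TitrationRecord:
    """One Winkler bottle titration."""

    bottle_id: str
    date: str
    treatment: str
    titrant_volume: float  # L
    bottle_volume: float = DEFAULT_BOTTLE_VOLUME  # L
    reagent_volume_displaced: float = DEFAULT_REAGENT_DISPLACED  # L
    thiosulfate_concentration: float = DEFAULT_THIOSULFATE_CONC  # mol/L

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.titrant_volume < 0:
            raise ValueError("titrant_volume must be >= 0")
        if self.reagent_volume_displaced >= self.bottle_volume:
            raise ValueError("displaced volume exceeds bottle volume")


@dataclass(frozen=True)
class OxygenConcentration:
    bottle_id: str
    date: str
    treatment: str
    value: float  # umol O2 / L


@dataclass
class RateEstimate:
    """A derived activity rate with its replicate-level uncertainty.

    ``value`` is positive for O2 consumption (respiration) and for net O2
    production (NPP); the sign convention is set by the deriving function.
    """

    analyte: str
    treatment: str
    date: str
    value: float
    units: str
    incubation_hours: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    replicate: int | None = None
    extra: dict = field(default_factory=dict)


def standardize_thiosulfate(
    records: list[StandardizationRecord],
) -> tuple[float, np.ndarray]:
    """Thiosulfate concentration (mol/L) from KIO3 standardisations.

    Each record yields ``6 * n(KIO3) / V(titrant)``; returns the mean and
    the per-replicate values.
    """
    if not records:
        raise ValueError("at least one standardization record required")
    per_rep = np.array(
        [THIOSULFATE_PER_IODATE * r.kio3_moles / r.titrant_volume for r in records]
    )
    return float(per_rep.mean()), per_rep


def o2_concentration(rec: TitrationRecord) -> OxygenConcentration:
    """Dissolved O2 (umol/L) from a bottle titration.

    The fixing reagents displace sample, so the effective sample volume is
    the bottle volume minus the displaced reagent volume.
    """
    v_eff = rec.bottle_volume - rec.reagent_volume_displaced
    if v_eff <= 0:
        raise ValueError("non-positive effective sample volume")
    mol_o2 = rec.titrant_volume * rec.thiosulfate_concentration / THIOSULFATE_PER_O2
    return OxygenConcentration(
        bottle_id=rec.bottle_id,
        date=rec.date,
        treatment=rec.treatment,
        value=mol_o2 / v_eff * 1e6,
    )


def titrant_volume_for_o2(
    o2_umol_per_l: float,
    bottle_volume: float = DEFAULT_BOTTLE_VOLUME,
    reagent_volume_displaced: float = DEFAULT_REAGENT_DISPLACED,
    thiosulfate_concentration: float = DEFAULT_THIOSULFATE_CONC,
) -> float:
    """Exact inverse of :func:`o2_concentration`: titrant volume (L) that
    would be recorded for a given O2 concentration."""
    v_eff = bottle_volume - reagent_volume_displaced
    return (
        o2_umol_per_l * 1e-6 * v_eff * THIOSULFATE_PER_O2 / thiosulfate_concentration
    )


def _diff_of_means(
    a: np.ndarray, b: np.ndarray, conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Welch interval for mean(a) - mean(b): (diff, lo, hi)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    diff = a.mean() - b.mean()
    if len(a) < 2 or len(b) < 2:
        return diff, np.nan, np.nan
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = np.sqrt(va + vb)
    if se == 0:
        return diff, diff, diff
    # Welch-Satterthwaite degrees of freedom
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    tcrit = stats.t.ppf(0.5 + conf_level / 2, df)
    return diff, diff - tcrit * se, diff + tcrit * se


def _as_values(concs: list[OxygenConcentration] | np.ndarray) -> np.ndarray:
    if len(concs) and isinstance(concs[0], OxygenConcentration):
        return np.array([c.value for c in concs])
    return np.asarray(concs, float)


def _check_dates(t0, end) -> str:
    dates = {c.date for c in list(t0) + list(end) if isinstance(c, OxygenConcentration)}
    if len(dates) > 1:
        raise ValueError(f"mismatched dates in rate calculation: {sorted(dates)}")
    return dates.pop() if dates else ""


def respiration_rate(
    t0: list[OxygenConcentration],
    end: list[OxygenConcentration],
    hours: float,
) -> RateEstimate:
    """Respiration (umol O2/L/h) from T0 and end-of-incubation bottles.

    Positive when O2 was consumed.  A negative rate (O2 increase in the
    dark) is retained with a warning rather than truncated, so downstream
    mixed models stay unbiased.  The 95% CI is a Welch t-interval on the
    difference of bottle means.
    """
    if hours <= 0:
        raise ValueError("incubation hours must be positive")
    if not len(t0) or not len(end):
        raise ValueError("need at least one T0 and one end bottle")
    date = _check_dates(t0, end)
    diff, lo, hi = _diff_of_means(_as_values(t0), _as_values(end))
    value = diff / hours
    if value < 0:
        warnings.warn(
            f"negative respiration rate ({value:.4g}) on {date or 'unknown date'}; "
            "retained",
            stacklevel=2,
        )
    treatment = end[0].treatment if isinstance(end[0], OxygenConcentration) else "dark"
    return RateEstimate(
        analyte="respiration",
        treatment=treatment,
        date=date,
        value=value,
        units="umol O2/L/h",
        incubation_hours=hours,
        ci_low=lo / hours,
        ci_high=hi / hours,
    )


def npp_rate(
    t0: list[OxygenConcentration],
    end_light: list[OxygenConcentration],
    hours: float,
) -> RateEstimate:
    """Net primary production (umol O2/L/h): net O2 gain in white light."""
    if hours <= 0:
        raise ValueError("incubation hours must be positive")
    if not len(t0) or not len(end_light):
        raise ValueError("need at least one T0 and one end bottle")
    date = _check_dates(t0, end_light)
    diff, lo, hi = _diff_of_means(_as_values(end_light), _as_values(t0))
    return RateEstimate(
        analyte="NPP",
        treatment="light",
        date=date,
        value=diff / hours,
        units="umol O2/L/h",
        incubation_hours=hours,
        ci_low=lo / hours,
        ci_high=hi / hours,
    )


def rates_from_titration_table(
    titrations: pd.DataFrame,
    standardizations: pd.DataFrame | None = None,
    hours: float = 24.0,
    apply_displacement_correction: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-date pipeline: titration table -> (O2 table, rate table).

    ``titrations`` columns: bottle_id, date, treatment, titrant_volume_ml,
    optionally bottle_volume_ml, thiosulfate_conc.  If ``standardizations``
    (columns kio3_umol, titrant_volume_ml) is given, the thiosulfate
    concentration is taken from it, overriding any per-row value.

    The rate table has one row per (date, treatment-derived analyte,
    replicate): respiration rates use each end bottle against the T0 mean
    so replicate bottles stay individual observations for the mixed model.
    """
    thio = None
    if standardizations is not None and len(standardizations):
        recs = [
            StandardizationRecord(
                kio3_moles=row.kio3_umol * 1e-6,
                titrant_volume=row.titrant_volume_ml * 1e-3,
                replicate=i,
            )
            for i, row in enumerate(standardizations.itertuples())
        ]
        thio, _ = standardize_thiosulfate(recs)

    disp = DEFAULT_REAGENT_DISPLACED if apply_displacement_correction else 0.0
    o2_rows = []
    for row in titrations.itertuples():
        rec = TitrationRecord(
            bottle_id=str(row.bottle_id),
            date=str(row.date),
            treatment=str(row.treatment),
            titrant_volume=row.titrant_volume_ml * 1e-3,
            bottle_volume=getattr(row, "bottle_volume_ml", 115.0) * 1e-3,
            reagent_volume_displaced=disp,
            thiosulfate_concentration=(
                thio
                if thio is not None
                else getattr(row, "thiosulfate_conc", DEFAULT_THIOSULFATE_CONC)
            ),
        )
        conc = o2_concentration(rec)
        o2_rows.append(
            {
                "bottle_id": conc.bottle_id,
                "date": conc.date,
                "treatment": conc.treatment,
                "o2_umol_per_l": conc.value,
            }
        )
    o2_table = pd.DataFrame(o2_rows)

    rate_rows = []
    for date, grp in o2_table.groupby("date", sort=True):
        t0 = grp.loc[grp.treatment == "T0", "o2_umol_per_l"].to_numpy()
        if not len(t0):
            raise ValueError(f"no T0 bottles on {date}")
        t0_mean = t0.mean()
        for treatment, analyte, sign in (
            ("dark", "respiration", 1.0),
            ("IR", "respiration", 1.0),
            ("light", "NPP", -1.0),
        ):
            vals = grp.loc[grp.treatment == treatment, "o2_umol_per_l"].to_numpy()
            for rep, v in enumerate(vals):
                rate_rows.append(
                    {
                        "analyte": analyte,
                        "date": date,
                        "treatment": treatment,
                        "replicate": rep,
                        "value": sign * (t0_mean - v) / hours,
                        "units": "umol O2/L/h",
                        "incubation_hours": hours,
                    }
                )
    return o2_table, pd.DataFrame(rate_rows)
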