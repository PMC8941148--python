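"""Synthetic bottle-, assay- and community-level datasets with known truth.

The generator emulates the field campaign's design: triplicate Winkler
bottles per treatment (T0 / dark / IR / white light) on each of ~16
sampling dates over two seasons, radiotracer monomer assays with killed
controls, fractionated bicarbonate incorporation, Gran titrations, and
an ASV count table whose composition covaries with temperature and AAP
abundance.

Generative model for activity rates (multiplicative treatment effects):

    y_ij(treatment) = mu_j * (1 + effect(treatment)) + eps_ij
    mu_j = mu_0 + b_j,  b_j ~ N(0, date_sd^2),  eps_ij ~ N(0, residual_sd^2)

Titration volumes are back-computed from the implied O2 concentrations
through the exact Winkler stoichiometry and then perturbed with
burette-reading noise; scintillation DPM are optionally drawn Poisson
around their expectation.  All randomness flows from one seeded
generator; the same seed reproduces every table byte for byte.

Default effect sizes and mean rates are the study conditions: a -15.2%
infrared effect on respiration, +18.1% / +9.5% / +5.9% on glucose /
pyruvate / leucine assimilation, no effect on thymidine or bicarbonate
incorporation, and dark means matching the observed seasonal averages.
Variance components (between-date and residual SDs) are calibration
choices, since the study reports only treatment contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import carbonate, io, radiotracer, winkler
from .budget import DEFAULT_LATITUDE, photoperiod

MONOMERS = ("glucose", "pyruvate", "leucine", "thymidine")

#: dark-treatment seasonal mean rates (nmol C/L/h) used as defaults
DEFAULT_MEAN_DARK_MONOMER = {
    "glucose": 0.55,
    "pyruvate": 12.67,
    "leucine": 0.36,
    "thymidine": 0.12,
}

DEFAULT_IR_EFFECTS = {
    "glucose": 0.181,
    "pyruvate": 0.095,
    "leucine": 0.059,
    "thymidine": 0.0,
    "bicarbonate": 0.0,
}

BICARB_FRACTION_SPLIT = {
    "particulate_gt2.5um": 0.45,
    "particulate_0.17_2.5um": 0.35,
    "doc_filtrate": 0.20,
}


@dataclass(frozen=True)
class CommunityConfig:
    """Dirichlet-multinomial community block."""

    n_asvs: int = 80
    n_samples: int = 24
    depth: int = 20000
    dispersion: float = 200.0  # Dirichlet concentration (higher = less noise)
    effect_sizes: dict = field(
        default_factory=lambda: {
            "temperature": 0.8,
            "aap_abundance": 0.6,
            "null_covariate": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.n_asvs < 1 or self.n_samples < 1:
            raise ValueError("counts must be >= 1")
        if self.depth < 100:
            raise ValueError("sequencing depth < 100 reads per sample")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters with the field campaign as defaults."""

    n_dates: int = 16
    replicates_per_treatment: int = 3
    true_ir_effect_respiration: float = -0.152
    true_ir_effect_by_substrate: dict = field(
        default_factory=lambda: dict(DEFAULT_IR_EFFECTS)
    )
    date_sd: float = 0.08  # between-date SD of the baseline (umol O2/L/h)
    residual_sd: float = 0.02  # within-date bottle SD (umol O2/L/h)
    titration_noise_sd_ml: float = 0.002  # burette reading noise
    dpm_counting: bool = True  # Poisson counting error on DPM
    mean_dark_respiration: float = 0.30  # umol O2/L/h
    mean_npp: float = 0.35  # umol O2/L/h in white light
    mean_dark_monomer: dict = field(
        default_factory=lambda: dict(DEFAULT_MEAN_DARK_MONOMER)
    )
    mean_co2_fixation: float = 0.06  # umol C/L/h (~5-fold below respiration)
    o2_baseline: float = 300.0  # umol O2/L at T0
    incubation_hours: float = 24.0
    monomer_hours: float = 1.0
    bicarb_hours: float = 4.0
    killed_control_dpm: float = 50.0
    total_added_dpm: float = 1.0e6
    ta_mol_per_l: float = 1.0e-3  # Gran-titration alkalinity
    ph: float = 8.3
    latitude: float = DEFAULT_LATITUDE
    community: CommunityConfig | None = field(default_factory=CommunityConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dates < 1 or self.replicates_per_treatment < 1:
            raise ValueError("counts must be >= 1")
        for sd in (self.date_sd, self.residual_sd, self.titration_noise_sd_ml):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        effects = [self.true_ir_effect_respiration] + list(
            self.true_ir_effect_by_substrate.values()
        )
        if any(abs(e) >= 1 for e in effects):
            raise ValueError("|effect| must be < 1")


@dataclass
class SimulatedStudy:
    """All generated tables plus the generating truth."""

    titration_table: pd.DataFrame
    standardization_table: pd.DataFrame
    scintillation_table: pd.DataFrame
    gran_table: pd.DataFrame
    station_table: pd.DataFrame
    covariate_table: pd.DataFrame
    count_table: pd.DataFrame | None
    truth: dict

    TABLE_NAMES = (
        "titration_table",
        "standardization_table",
        "scintillation_table",
        "gran_table",
        "station_table",
        "covariate_table",
        "count_table",
    )

    def write(self, outdir, provenance: dict | None = None) -> None:
        outdir = Path(outdir)
        for name in self.TABLE_NAMES:
            df = getattr(self, name)
            if df is not None:
                io.write_table(df, outdir / f"{name}.csv", provenance)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)

    @classmethod
    def read(cls, indir) -> "SimulatedStudy":
        indir = Path(indir)
        kwargs = {}
        for name in cls.TABLE_NAMES:
            path = indir / f"{name}.csv"
            kwargs[name] = io.read_table(path) if path.exists() else None
        with open(indir / "truth.json") as fh:
            truth = json.load(fh)
        return cls(truth=truth, **kwargs)


def _check_feasible(cfg: SimConfig) -> None:
    """Reject configurations where negative rates or titrant volumes have
    probability > 1% at the configured noise."""
    sd_tot = np.hypot(cfg.date_sd, cfg.residual_sd)
    checks = {
        "dark respiration": cfg.mean_dark_respiration,
        "IR respiration": cfg.mean_dark_respiration
        * (1 + cfg.true_ir_effect_respiration),
        "NPP": cfg.mean_npp,
    }
    for label, mu in checks.items():
        if sd_tot > 0 and stats.norm.cdf(0.0, mu, sd_tot) > 0.01:
            raise ValueError(
                f"unusable scenario: P({label} < 0) > 1% at the configured noise"
            )
    cv = sd_tot / cfg.mean_dark_respiration if cfg.mean_dark_respiration else 0.0
    for sub, mu in cfg.mean_dark_monomer.items():
        if cv > 0 and stats.norm.cdf(0.0, mu, cv * mu) > 0.01:
            raise ValueError(f"unusable scenario: P({sub} rate < 0) > 1%")
    # titrant volume for the lowest plausible O2 (end of dark incubation)
    o2_end = cfg.o2_baseline - (
        checks["dark respiration"] + 3 * sd_tot
    ) * cfg.incubation_hours
    vt_ml = winkler.titrant_volume_for_o2(o2_end) * 1e3
    if cfg.titration_noise_sd_ml > 0 and (
        stats.norm.cdf(0.0, vt_ml, cfg.titration_noise_sd_ml) > 0.01
    ):
        raise ValueError("unusable scenario: P(titrant volume < 0) > 1%")


def _sampling_dates(cfg: SimConfig) -> pd.DatetimeIndex:
    """Roughly monthly dates April-November across as many years as needed."""
    dates = []
    year = 2018
    month = 4
    for _ in range(cfg.n_dates):
        dates.append(pd.Timestamp(year=year, month=month, day=15))
        month += 1
        if month > 11:
            month, year = 4, year + 1
    return pd.DatetimeIndex(dates)


def _seasonal_temperature(dates: pd.DatetimeIndex) -> np.ndarray:
    doy = np.array([d.dayofyear for d in dates], float)
    return 14.0 + 9.0 * np.sin(2 * np.pi * (doy - 110.0) / 365.0)


def simulate_activity(cfg: SimConfig) -> SimulatedStudy:
    """Generate all bottle- and assay-level tables for one study.

    Returns a :class:`SimulatedStudy`; ``truth`` records per-date baseline
    means and the configured treatment effects so recovery can be tested.
    """
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    dates = _sampling_dates(cfg)
    date_str = [d.strftime("%Y-%m-%d") for d in dates]
    temps = _seasonal_temperature(dates)
    reps = cfg.replicates_per_treatment

    b = rng.normal(0.0, cfg.date_sd, cfg.n_dates)
    mu_resp = cfg.mean_dark_respiration + b
    # NPP and monomer baselines share the date effect as a common CV
    rel = 1.0 + b / cfg.mean_dark_respiration
    mu_npp = cfg.mean_npp * rel
    eff_resp = cfg.true_ir_effect_respiration
    cv_res = cfg.residual_sd / cfg.mean_dark_respiration

    # --- Winkler bottles --------------------------------------------------
    stand_rows = []
    for i in range(3):
        vol = 0.6 + rng.normal(0.0, cfg.titration_noise_sd_ml)
        stand_rows.append(
            {"replicate": i, "kio3_umol": 1.0, "titrant_volume_ml": vol}
        )
    standardization = pd.DataFrame(stand_rows)

    tit_rows = []
    for j, date in enumerate(date_str):
        targets = {"T0": np.full(reps, cfg.o2_baseline)}
        rate_dark = mu_resp[j] + rng.normal(0, cfg.residual_sd, reps)
        rate_ir = mu_resp[j] * (1 + eff_resp) + rng.normal(0, cfg.residual_sd, reps)
        rate_npp = mu_npp[j] + rng.normal(0, cv_res * cfg.mean_npp, reps)
        targets["dark"] = cfg.o2_baseline - rate_dark * cfg.incubation_hours
        targets["IR"] = cfg.o2_baseline - rate_ir * cfg.incubation_hours
        targets["light"] = cfg.o2_baseline + rate_npp * cfg.incubation_hours
        for treatment, o2 in targets.items():
            for r in range(reps):
                vt_ml = winkler.titrant_volume_for_o2(o2[r]) * 1e3
                vt_ml += rng.normal(0.0, cfg.titration_noise_sd_ml)
                tit_rows.append(
                    {
                        "bottle_id": f"{date}-{treatment}-{r}",
                        "date": date,
                        "treatment": treatment,
                        "replicate": r,
                        "titrant_volume_ml": vt_ml,
                        "bottle_volume_ml": 115.0,
                    }
                )
    titration = pd.DataFrame(tit_rows)

    # --- radiotracer assays ----------------------------------------------
    def maybe_count(expected: float) -> float:
        if cfg.dpm_counting:
            return float(rng.poisson(max(expected, 0.0)))
        return expected

    dic_by_date = np.array(
        [
            carbonate.dic_from_ta(
                float(np.clip(t, 0.0, 40.0)), cfg.ph, cfg.ta_mol_per_l
            ).dic
            for t in temps
        ]
    )
    scin_rows = []
    for j, date in enumerate(date_str):
        dic_truth = dic_by_date[j]
        for sub in MONOMERS:
            mu_sub = cfg.mean_dark_monomer[sub] * rel[j]
            eff = cfg.true_ir_effect_by_substrate.get(sub, 0.0)
            assay_kw = dict(
                substrate=sub,
                specific_activity=radiotracer.DEFAULT_SPECIFIC_ACTIVITY[sub],
                incubation_hours=cfg.monomer_hours,
                date=date,
            )
            res_sd = cv_res * cfg.mean_dark_monomer[sub]  # constant per analyte
            for treatment, mult in (("dark", 1.0), ("IR", 1.0 + eff)):
                rates = mu_sub * mult + rng.normal(0, res_sd, reps)
                for r in range(reps):
                    assay = radiotracer.TracerAssay(
                        treatment=treatment, replicate=r, **assay_kw
                    )
                    expected = radiotracer.expected_dpm(
                        assay, rates[r], cfg.killed_control_dpm
                    )
                    scin_rows.append(
                        {
                            "date": date,
                            "substrate": sub,
                            "treatment": treatment,
                            "replicate": r,
                            "fraction": "whole",
                            "dpm": maybe_count(expected),
                            "killed_dpm": maybe_count(cfg.killed_control_dpm),
                            "specific_activity_gbq_mmol": assay.specific_activity,
                            "sample_volume_ml": assay.sample_volume * 1e3,
                            "incubation_hours": cfg.monomer_hours,
                        }
                    )
        # fractionated bicarbonate incorporation, both treatments
        eff_bic = cfg.true_ir_effect_by_substrate.get("bicarbonate", 0.0)
        total_dpm_per_l = (
            cfg.total_added_dpm / radiotracer.DEFAULT_TOTAL_ALIQUOT_VOLUME
        )
        for treatment, mult in (("dark", 1.0), ("IR", 1.0 + eff_bic)):
            rates = cfg.mean_co2_fixation * rel[j] * mult + rng.normal(
                0, cv_res * cfg.mean_co2_fixation, reps
            )
            for r in range(reps):
                for frac, share in BICARB_FRACTION_SPLIT.items():
                    vol = radiotracer.DEFAULT_FRACTION_VOLUMES[frac]
                    inc_frac = (
                        rates[r] * share * cfg.bicarb_hours / (dic_truth * 1e6)
                    )
                    expected = inc_frac * total_dpm_per_l * vol
                    scin_rows.append(
                        {
                            "date": date,
                            "substrate": "bicarbonate",
                            "treatment": treatment,
                            "replicate": r,
                            "fraction": frac,
                            "dpm": maybe_count(expected),
                            "killed_dpm": 0.0,
                            "specific_activity_gbq_mmol": np.nan,
                            "sample_volume_ml": vol * 1e3,
                            "incubation_hours": cfg.bicarb_hours,
                        }
                    )
                scin_rows.append(
                    {
                        "date": date,
                        "substrate": "bicarbonate",
                        "treatment": treatment,
                        "replicate": r,
                        "fraction": "total_added",
                        "dpm": cfg.total_added_dpm,
                        "killed_dpm": 0.0,
                        "specific_activity_gbq_mmol": np.nan,
                        "sample_volume_ml": (
                            radiotracer.DEFAULT_TOTAL_ALIQUOT_VOLUME * 1e3
                        ),
                        "incubation_hours": cfg.bicarb_hours,
                    }
                )
    scintillation = pd.DataFrame(scin_rows)

    # --- Gran titrations (noise-free forward model) -----------------------
    gran_rows = []
    for j, date in enumerate(date_str):
        t = carbonate.simulate_gran_titration(
            dic=cfg.ta_mol_per_l,
            temperature=float(np.clip(temps[j], 0.0, 40.0)),
        )
        for va, ph in zip(t.acid_volumes, t.ph):
            gran_rows.append(
                {
                    "date": date,
                    "sample_volume_ml": t.sample_volume * 1e3,
                    "acid_conc_mol_l": t.acid_concentration,
                    "acid_volume_ml": va * 1e3,
                    "ph": ph,
                }
            )
    gran = pd.DataFrame(gran_rows)

    station = pd.DataFrame(
        {
            "date": date_str,
            "temperature_c": temps,
            "ph": cfg.ph,
            "light_hours": [photoperiod(d, cfg.latitude) for d in dates],
            "latitude": cfg.latitude,
        }
    )

    covariates, counts = (None, None)
    if cfg.community is not None:
        covariates, counts = simulate_community(cfg, rng=rng, temperatures=temps)
    else:
        covariates = pd.DataFrame({"date": date_str, "temperature": temps})

    truth = {
        "config": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("community",)
        },
        "date_baseline_respiration": dict(zip(date_str, mu_resp.tolist())),
        "ir_effect_respiration": eff_resp,
        "ir_effect_by_substrate": dict(cfg.true_ir_effect_by_substrate),
        "dic_mol_per_l": dict(zip(date_str, dic_by_date.tolist())),
    }
    return SimulatedStudy(
        titration_table=titration,
        standardization_table=standardization,
        scintillation_table=scintillation,
        gran_table=gran,
        station_table=station,
        covariate_table=covariates,
        count_table=counts,
        truth=truth,
    )


def simulate_community(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    temperatures: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial count table whose log-relative-abundance
    means shift linearly with the configured covariates.

    Returns (covariate_table, count_table).  A null covariate with zero
    effect is always present so type-I behaviour can be checked.
    """
    if cfg.community is None:
        raise ValueError("community block absent from config")
    com = cfg.community
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, k = com.n_samples, com.n_asvs

    z = {}
    if temperatures is not None and len(temperatures) == n:
        z["temperature"] = np.asarray(temperatures, float)
    else:
        z["temperature"] = rng.normal(15.0, 5.0, n)
    z["aap_abundance"] = np.exp(rng.normal(0.0, 0.5, n)) * 1e5  # cells/mL
    z["null_covariate"] = rng.normal(0.0, 1.0, n)
    covariates = pd.DataFrame({"sample": [f"S{i:02d}" for i in range(n)], **z})

    base = rng.normal(0.0, 1.0, k)
    eta = np.tile(base, (n, 1))
    for name, effect in com.effect_sizes.items():
        if name not in z or effect == 0.0:
            continue
        zc = (z[name] - np.mean(z[name])) / np.std(z[name])
        loadings = rng.normal(0.0, 1.0, k)
        eta += effect * np.outer(zc, loadings)
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    counts = np.empty((n, k), dtype=int)
    for i in range(n):
        pi = rng.dirichlet(com.dispersion * p[i])
        counts[i] = rng.multinomial(com.depth, pi)
    count_table = pd.DataFrame(
        counts,
        index=covariates["sample"],
        columns=[f"ASV{j:04d}" for j in range(k)],
    )
    return covariates, count_table
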