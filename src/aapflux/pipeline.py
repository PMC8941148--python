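"""End-to-end analysis pipeline: raw tables -> rates -> light effects ->
seasonal budget -> community model.

Every stage consumes and emits plain CSV tables (with provenance
headers) so any stage can also be run standalone through the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import carbonate, community, io, mixedlm, radiotracer, simulate, winkler

logger = logging.getLogger("aapflux")

ANALYTE_ORDER = (
    "respiration",
    "CO2_fixation",
    "glucose",
    "pyruvate",
    "leucine",
    "thymidine",
)


def dic_table(gran: pd.DataFrame, station: pd.DataFrame) -> pd.DataFrame:
    """Per-date alkalinity (Gran) and DIC (speciation) from titration
    points plus station temperature/pH."""
    meta = station.set_index(station["date"].astype(str))
    rows = []
    for date, grp in gran.groupby("date", sort=True):
        t = carbonate.GranTitration(
            sample_volume=float(grp["sample_volume_ml"].iloc[0]) * 1e-3,
            acid_concentration=float(grp["acid_conc_mol_l"].iloc[0]),
            acid_volumes=grp["acid_volume_ml"].to_numpy() * 1e-3,
            ph=grp["ph"].to_numpy(),
        )
        gres = carbonate.gran_alkalinity(t)
        m = meta.loc[str(date)]
        sys = carbonate.dic_from_ta(
            float(np.clip(m["temperature_c"], 0.0, 40.0)), float(m["ph"]), gres.ta
        )
        rows.append(
            {
                "date": date,
                "ta_mol_per_l": gres.ta,
                "gran_r_squared": gres.r_squared,
                "dic_mol_per_l": sys.dic,
            }
        )
    return pd.DataFrame(rows)


def tracer_rates(
    scintillation: pd.DataFrame, dic: pd.DataFrame
) -> pd.DataFrame:
    """Long rate table from a scintillation table (monomer 'whole' rows
    and fractionated bicarbonate rows)."""
    dic_by_date = dic.set_index(dic["date"].astype(str))["dic_mol_per_l"]
    rows = []
    monomers = scintillation[scintillation.substrate != "bicarbonate"]
    for r in monomers.itertuples():
        assay = radiotracer.TracerAssay(
            substrate=r.substrate,
            specific_activity=r.specific_activity_gbq_mmol,
            incubation_hours=r.incubation_hours,
            treatment=r.treatment,
            date=str(r.date),
            sample_volume=r.sample_volume_ml * 1e-3,
            replicate=int(r.replicate),
        )
        est = radiotracer.monomer_rate(assay, r.dpm, r.killed_dpm)
        rows.append(
            {
                "analyte": est.analyte,
                "date": est.date,
                "treatment": est.treatment,
                "replicate": est.replicate,
                "value": est.value,
                "units": est.units,
                "incubation_hours": est.incubation_hours,
            }
        )
    bic = scintillation[scintillation.substrate == "bicarbonate"]
    for (date, treatment, rep), grp in bic.groupby(
        ["date", "treatment", "replicate"], sort=True
    ):
        total = grp[grp.fraction == "total_added"]
        fracs = grp[grp.fraction != "total_added"]
        if not len(total):
            raise ValueError(f"missing total_added row for {date}/{treatment}/{rep}")
        assay = radiotracer.TracerAssay(
            substrate="bicarbonate",
            specific_activity=1.0,  # unused for bicarbonate bookkeeping
            incubation_hours=float(fracs["incubation_hours"].iloc[0]),
            treatment=str(treatment),
            date=str(date),
            carbons_per_molecule=1,
            replicate=int(rep),
        )
        records = [
            radiotracer.ScintillationRecord(
                fraction=fr.fraction, dpm=fr.dpm, volume=fr.sample_volume_ml * 1e-3
            )
            for fr in fracs.itertuples()
        ]
        _, tot = radiotracer.bicarbonate_rates(
            assay,
            records,
            total_added_dpm=float(total["dpm"].iloc[0]),
            dic=float(dic_by_date.loc[str(date)]),
            total_aliquot_volume=float(total["sample_volume_ml"].iloc[0]) * 1e-3,
        )
        rows.append(
            {
                "analyte": tot.analyte,
                "date": tot.date,
                "treatment": tot.treatment,
                "replicate": tot.replicate,
                "value": tot.value,
                "units": tot.units,
                "incubation_hours": tot.incubation_hours,
            }
        )
    return pd.DataFrame(rows)


def rates_from_study(study: simulate.SimulatedStudy) -> pd.DataFrame:
    """Full rate derivation: Winkler + carbonate + tracer stages."""
    _, o2_rates = winkler.rates_from_titration_table(
        study.titration_table, study.standardization_table
    )
    dic = dic_table(study.gran_table, study.station_table)
    tr = tracer_rates(study.scintillation_table, dic)
    return pd.concat([o2_rates, tr], ignore_index=True)


def light_effect_summaries(rates: pd.DataFrame) -> pd.DataFrame:
    """Percent dark-vs-IR difference with 95% CI and LRT p per analyte."""
    rows = []
    for analyte in [a for a in ANALYTE_ORDER if a in set(rates.analyte)]:
        sub = rates[
            (rates.analyte == analyte) & rates.treatment.isin(["dark", "IR"])
        ]
        if sub.treatment.nunique() < 2:
            continue
        _, summ = mixedlm.fit_light_effect(sub, analyte=analyte)
        rows.append(
            {
                "analyte": analyte,
                "percent_difference": summ.percent,
                "ci_low": summ.ci_low,
                "ci_high": summ.ci_high,
                "direction": summ.direction,
                "p_value": summ.p_value,
            }
        )
    return pd.DataFrame(rows)


def seasonal_budget(
    rates: pd.DataFrame,
    station: pd.DataFrame,
    cfg: budget_mod.SeasonConfig | None = None,
) -> budget_mod.SeasonBudget:
    cfg = cfg or budget_mod.SeasonConfig()
    days = budget_mod.station_days_from_tables(rates, station)
    return budget_mod.budget_difference(days, cfg)


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(
    outdir,
    sim_config: simulate.SimConfig | None = None,
    input_dir=None,
    season_config: budget_mod.SeasonConfig | None = None,
    distlm_perms: int = 999,
    seed: int | None = None,
) -> dict:
    """Execute simulate -> winkler -> carbonate -> tracer -> lmm ->
    budget -> community and write all stage outputs under ``outdir``.

    Either ``sim_config`` (generate data) or ``input_dir`` (read a table
    directory written by :meth:`SimulatedStudy.write`) must be given.
    Returns a dict of headline results; partial outputs are preserved if
    a stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim_config is None and input_dir is None:
        raise ValueError("need sim_config or input_dir")
    if seed is not None and sim_config is not None:
        sim_config = replace(sim_config, seed=seed)

    stage = "simulate"
    try:
        if sim_config is not None:
            study = simulate.simulate_activity(sim_config)
            prov = {"stage": "simulate", "seed": sim_config.seed}
            study.write(outdir / "tables", provenance=prov)
        else:
            study = simulate.SimulatedStudy.read(input_dir)
        logger.info("stage=simulate n_dates=%d", study.station_table.shape[0])

        prov = {"stage": "", "seed": seed if seed is not None else "n/a"}

        stage = "winkler"
        o2, o2_rates = winkler.rates_from_titration_table(
            study.titration_table, study.standardization_table
        )
        prov["stage"] = stage
        io.write_table(o2, outdir / "o2_concentrations.csv", prov)

        stage = "carbonate"
        dic = dic_table(study.gran_table, study.station_table)
        prov["stage"] = stage
        io.write_table(dic, outdir / "dic.csv", prov)

        stage = "tracer"
        tr = tracer_rates(study.scintillation_table, dic)
        rates = pd.concat([o2_rates, tr], ignore_index=True)
        prov["stage"] = stage
        io.write_table(rates, outdir / "rates.csv", prov)

        stage = "lmm"
        effects = light_effect_summaries(rates)
        prov["stage"] = stage
        io.write_table(effects, outdir / "light_effects.csv", prov)

        stage = "budget"
        sb = seasonal_budget(rates, study.station_table, season_config)
        summary = sb.summary()
        summary["difference_dark_minus_ir_g_co2"] = sb.difference_dark_minus_ir
        prov["stage"] = stage
        io.write_table(summary, outdir / "budget.csv", prov)

        distlm_summary = None
        if study.count_table is not None:
            stage = "community"
            counts = study.count_table
            if "sample" in counts.columns:
                counts = counts.set_index("sample")
            try:
                filtered = community.rare_filter(counts)
            except ValueError:
                filtered = counts
            dm = community.bray_curtis(community.vst(filtered))
            preds = study.covariate_table.drop(
                columns=[c for c in ("sample", "date") if c in study.covariate_table],
            )
            res = community.DistLM(dm, preds).fit(n_perms=distlm_perms, seed=seed)
            prov["stage"] = stage
            io.write_table(res.marginal, outdir / "distlm_marginal.csv", prov)
            io.write_table(res.sequential, outdir / "distlm_sequential.csv", prov)
            distlm_summary = res.marginal.to_dict("records")
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc

    results = {
        "light_effects": effects.to_dict("records"),
        "budget_g_co2": {
            "npp": sb.npp,
            "respiration_dark": sb.respiration_dark,
            "respiration_ir": sb.respiration_ir,
            "difference_dark_minus_ir": sb.difference_dark_minus_ir,
        },
        "distlm_marginal": distlm_summary,
        "seed": seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results
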