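"""Data contracts, CSV round-tripping and the end-to-end pipeline.

The canonical on-disk format is a long (one row per sample) RFC-4180 CSV
with columns subject_id, age_group, sex, bw_kg, occasion, dose_number,
analyte, time_min, conc_ug_per_ml, blq_flag; ``time_min`` is minutes
after the occasion's own dose.  ``run_pipeline`` wires the stages in the
analysis order: cohort -> LOQ filter -> IV fits -> oral fits with the
inversion clearance frozen -> NCA / bioavailability -> accumulation ->
renal markers -> group summaries -> allometry.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import allometry, estimation, nca
from .cohort import (
    AGE_GROUPS,
    CohortSpec,
    ErrorModel,
    derive_total_records,
    generate_cohort,
)
from .model import DoseEvent, ValidationError

__all__ = [
    "REQUIRED_COLUMNS",
    "read_table",
    "write_table",
    "read_config",
    "run_pipeline",
]

log = logging.getLogger("chiralpk")

REQUIRED_COLUMNS = (
    "subject_id",
    "age_group",
    "sex",
    "bw_kg",
    "occasion",
    "analyte",
    "time_min",
    "conc_ug_per_ml",
    "blq_flag",
)

OCCASIONS = ("iv", "po_dose1", "po_sparse", "po_dose13", "marker_day1", "marker_day2")


def read_table(path) -> pd.DataFrame:
    """Read and validate a long-format study table."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if "dose_number" not in df.columns:
        df["dose_number"] = 1
    bad_occ = set(df["occasion"]) - set(OCCASIONS)
    if bad_occ:
        raise ValidationError(f"{path}: unknown occasion(s) {sorted(bad_occ)}")
    if (df["conc_ug_per_ml"].fillna(0) < 0).any():
        raise ValidationError(f"{path}: negative concentrations present")
    df["blq_flag"] = df["blq_flag"].astype(bool)
    keys = ["subject_id", "occasion", "dose_number", "analyte", "time_min"]
    if df.duplicated(keys).any():
        raise ValidationError(f"{path}: duplicate records for key {keys}")
    return df


def write_table(table: pd.DataFrame, path) -> None:
    """Write a study table as CSV (round-trips through :func:`read_table`)."""
    table.to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _spec_from_config(config: dict) -> CohortSpec:
    kw = {}
    for key in ("n_per_group", "dose_racemic", "include_markers", "seed"):
        if key in config:
            kw[key] = config[key]
    if "error" in config:
        kw["error"] = ErrorModel(**config["error"])
    return CohortSpec(**kw)


def _subject_fits(records, dose_racemic, stages):
    """Sequential per-subject fits; returns one row per subject."""
    iv_dose = DoseEvent(0.0, "iv", dose_racemic)
    po_dose = DoseEvent(0.0, "oral", dose_racemic)
    rows = []
    for sid, sub in records.groupby("subject_id", sort=False):
        meta = sub.iloc[0]
        row = {
            "subject_id": sid,
            "age_group": meta["age_group"],
            "sex": meta["sex"],
            "bw_kg": meta["bw_kg"],
        }
        iv_fit = None
        if "iv" in stages:
            try:
                # floor of 4 points per enantiomer: fast-clearing subjects
                # legitimately retain < 6 quantifiable R samples
                res = estimation.fit_iv_enantiomers(
                    sub[sub["occasion"] == "iv"], iv_dose, min_obs=4
                )
                iv_fit = res.params
                row.update(
                    V_R=iv_fit.V_R, Cl_R=iv_fit.Cl_R, Cl_RtoS=iv_fit.Cl_RtoS,
                    V_S=iv_fit.V_S, Cl_S=iv_fit.Cl_S, iv_converged=res.converged,
                )
            except ValidationError as exc:
                log.warning("IV fit skipped for %s: %s", sid, exc)
        if "oral" in stages:
            if "iv" not in stages:
                raise ValidationError(
                    "oral stage requires the IV stage (frozen Cl_RtoS missing)"
                )
            if iv_fit is None:
                log.warning("oral fit skipped for %s: no IV estimates", sid)
                rows.append(row)
                continue
            try:
                res = estimation.fit_oral_enantiomers(
                    sub[sub["occasion"] == "po_dose1"], po_dose,
                    cl_r_to_s=iv_fit.Cl_RtoS, iv_params=iv_fit,
                )
                row.update(
                    ka_R=res.params.ka_R, ka_S=res.params.ka_S,
                    F_R=res.params.F_R, F_S=res.params.F_S,
                    oral_converged=res.converged,
                )
            except ValidationError as exc:
                log.warning("oral fit skipped for %s: %s", sid, exc)
        if "total" in stages:
            try:
                res = estimation.fit_total_one_compartment(
                    sub[sub["occasion"] == "iv"], iv_dose
                )
                row.update(Cl_total=res.params.Cl, V_total=res.params.V)
            except ValidationError as exc:
                log.warning("total fit skipped for %s: %s", sid, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _subject_nca(records, dose_racemic):
    """Per-subject, per-analyte NCA, bioavailability and accumulation."""
    rows = []
    for (sid, analyte), sub in records[
        records["analyte"].isin(["R", "S", "total"])
    ].groupby(["subject_id", "analyte"], sort=False):
        meta = sub.iloc[0]
        row = {
            "subject_id": sid,
            "age_group": meta["age_group"],
            "analyte": analyte,
        }
        profiles = {}
        for occ in ("iv", "po_dose1", "po_dose13"):
            p = sub[sub["occasion"] == occ].sort_values("time_min")
            if len(p) >= 2:
                profiles[occ] = (
                    p["time_min"].to_numpy(float),
                    p["conc_ug_per_ml"].to_numpy(float),
                )
        for occ, (t, c) in profiles.items():
            res = nca.nca_profile(t, c, auc_t_end=min(180.0, t[-1]))
            row[f"cmax_{occ}"] = res.Cmax
            row[f"tmax_{occ}"] = res.Tmax
            row[f"auc3h_{occ}"] = res.AUC_0_t
            row[f"auc_inf_{occ}"] = res.AUC_0_inf
            row[f"t_half_{occ}"] = res.t_half
        if "iv" in profiles and "po_dose1" in profiles:
            try:
                f = nca.absolute_bioavailability(
                    *profiles["po_dose1"], *profiles["iv"], dose_racemic, dose_racemic,
                    require_coverage=False,
                )
                row["F_nca"] = f.F
            except ValidationError:
                pass
        if "po_dose1" in profiles and "po_dose13" in profiles:
            try:
                acc = nca.accumulation_ratio(*profiles["po_dose1"], *profiles["po_dose13"])
                row["accumulation_ratio"] = acc.ratio
            except ValidationError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def _marker_fits(records):
    rows = []
    for sid, sub in records.groupby("subject_id", sort=False):
        meta = sub.iloc[0]
        row = {"subject_id": sid, "age_group": meta["age_group"], "bw_kg": meta["bw_kg"]}
        for occ in ("marker_day1", "marker_day2"):
            osub = sub[sub["occasion"] == occ]
            day = occ[-4:]
            try:
                gfr = estimation.fit_iohexol_gfr(osub)
                row[f"gfr_{day}"] = gfr.extras["gfr"]
            except Exception as exc:  # keep the pipeline running
                log.warning("iohexol fit skipped for %s/%s: %s", sid, occ, exc)
            try:
                erpf = estimation.fit_pah_erpf(osub)
                row[f"erpf_{day}"] = erpf.extras["erpf"]
            except Exception as exc:
                log.warning("PAH fit skipped for %s/%s: %s", sid, occ, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if {"gfr_day1", "gfr_day2"} <= set(df.columns):
        df["gfr_paired_diff"] = df["gfr_day2"] - df["gfr_day1"]
    return df


def _allometry_tables(fits: pd.DataFrame) -> pd.DataFrame:
    """Group-mean allometric exponents of whole-body total Cl and V."""
    rows = []
    grp = fits.groupby("age_group", sort=False).agg(
        bw=("bw_kg", "mean"), cl=("Cl_total", "mean"), v=("V_total", "mean")
    ).reindex([g for g in AGE_GROUPS if g in set(fits["age_group"])])
    for name, col in (("Cl_total", "cl"), ("V_total", "v")):
        y = allometry.whole_body(grp[col].to_numpy(), grp["bw"].to_numpy())
        fit = allometry.fit_power_law(grp["bw"].to_numpy(), y)
        rows.append(
            {
                "parameter": name,
                "covariate": "bw",
                "exponent": fit.exponent,
                "intercept_ln": fit.intercept_ln,
                "r": fit.r,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_STAGES = ("cohort", "iv", "oral", "total", "nca", "renal", "allometry")


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run the full analysis on a freshly generated virtual cohort.

    ``config`` keys (all optional): seed, n_per_group, dose_racemic,
    error {proportional_sd, additive_sd, loq}, include_markers, stages.
    Returns a bundle of DataFrames; with ``outdir`` each stage is also
    written as CSV together with a small run log.
    """
    config = dict(config or {})
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    spec = _spec_from_config(config)
    subjects, records = generate_cohort(spec)
    records = pd.concat(
        [records, derive_total_records(records, loq=spec.error.loq)], ignore_index=True
    )
    filtered, n_blq = nca.apply_loq_filter(records, loq=spec.error.loq)
    log.info("generated %d records, %d excluded below LOQ", len(records), n_blq)

    results: dict = {
        "subjects": subjects,
        "records": records,
        "filtered": filtered,
        "n_blq_excluded": n_blq,
        "seed": spec.seed,
    }
    if {"iv", "oral", "total"} & set(stages):
        fits = _subject_fits(filtered, spec.dose_racemic, stages)
        results["fits"] = fits
        value_cols = [
            c for c in ("V_R", "Cl_R", "Cl_RtoS", "V_S", "Cl_S",
                        "ka_R", "ka_S", "F_R", "F_S", "Cl_total", "V_total")
            if c in fits.columns
        ]
        results["summary"] = estimation.summarize_group(fits, value_cols)
    if "nca" in stages:
        results["nca"] = _subject_nca(filtered, spec.dose_racemic)
    if "renal" in stages and spec.include_markers:
        results["renal"] = _marker_fits(filtered)
    if "allometry" in stages and "fits" in results and "Cl_total" in results["fits"]:
        results["allometry"] = _allometry_tables(results["fits"])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "seed": spec.seed,
                    "stages": list(stages),
                    "n_records": int(len(records)),
                    "n_blq_excluded": int(n_blq),
                    "spec": {
                        "n_per_group": spec.n_per_group,
                        "dose_racemic": spec.dose_racemic,
                        "error": dataclasses.asdict(spec.error),
                    },
                },
                fh,
            )
    return results
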