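"""Virtual study cohorts with the trial's design and variability structure.

Generates synthetic plasma concentration data for four porcine age groups
(1 week, 4 weeks, 8 weeks, 6-7 months; neonate/infant/child/adolescent
analogues), eight treated pigs per group (4 male / 4 female), under the
study regimen: a single 5 mg/kg IV bolus of the racemate, then 5 mg/kg
orally three times daily for five days (6-h intervals within the day),
with rich sampling on the IV day and around oral doses 1 and 13, trough +
30 min sampling otherwise, and renal-marker (iohexol, PAH) profiles on
two occasions.

Between-subject variability is log-normal around the published group
means with moment-matched arithmetic mean/SD; residual error is combined
proportional + additive; observations below the 0.25 ug/mL LOQ are
flagged BLQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    IOHEXOL_DOSE_MG_PER_KG,
    PAH_DOSE_MG_PER_KG,
    TwoCompartmentParams,
    two_compartment_curve,
)
from .model import (
    DoseEvent,
    EnantiomerParams,
    Regimen,
    ValidationError,
    simulate_iv_bolus,
    simulate_oral,
    simulate_regimen,
)
from .nca import LOQ_UG_PER_ML

__all__ = [
    "AGE_GROUPS",
    "GroupSpec",
    "ErrorModel",
    "SamplingSchedule",
    "CohortSpec",
    "draw_subjects",
    "simulate_cohort",
    "generate_cohort",
    "derive_total_records",
    "make_study_config",
    "TABLE2_GROUPS",
]

AGE_GROUPS = ("1wk", "4wk", "8wk", "6-7mo")


@dataclass(frozen=True)
class GroupSpec:
    """Generating mean and between-subject SD for one age group.

    Enantiomer parameters are the published group summaries (IV occasion
    for disposition, first oral dose for absorption); F is a fraction.
    Renal-marker clearances are realistic porcine defaults (the source
    summaries were graphical only).
    """

    bw_kg: tuple[float, float]
    V_R: tuple[float, float]
    Cl_R: tuple[float, float]
    Cl_RtoS: tuple[float, float]
    V_S: tuple[float, float]
    Cl_S: tuple[float, float]
    ka_R: tuple[float, float]
    ka_S: tuple[float, float]
    F_R: tuple[float, float]
    F_S: tuple[float, float]
    gfr: tuple[float, float] = (2.5, 0.5)
    erpf: tuple[float, float] = (12.0, 2.4)


#: Generating settings per age group (disposition/absorption summaries of
#: the pig study; marker clearances are package defaults).
TABLE2_GROUPS: dict[str, GroupSpec] = {
    "1wk": GroupSpec(
        bw_kg=(3.0, 0.4),
        V_R=(329.9, 58.8), Cl_R=(10.6, 2.7), Cl_RtoS=(9.3, 2.1),
        V_S=(248.5, 26.2), Cl_S=(1.9, 0.6),
        ka_R=(0.1, 0.1), ka_S=(0.07, 0.07),
        F_R=(1.262, 0.468), F_S=(0.869, 0.226),
        gfr=(2.0, 0.4), erpf=(9.0, 1.8),
    ),
    "4wk": GroupSpec(
        bw_kg=(7.0, 0.8),
        V_R=(259.5, 41.4), Cl_R=(5.3, 1.8), Cl_RtoS=(4.6, 1.5),
        V_S=(233.6, 90.6), Cl_S=(2.6, 0.7),
        ka_R=(0.08, 0.1), ka_S=(0.06, 0.08),
        F_R=(0.679, 0.338), F_S=(0.835, 0.389),
        gfr=(2.5, 0.5), erpf=(12.0, 2.4),
    ),
    "8wk": GroupSpec(
        bw_kg=(20.1, 3.4),
        V_R=(296.0, 64.7), Cl_R=(7.5, 1.0), Cl_RtoS=(3.9, 0.7),
        V_S=(275.4, 64.4), Cl_S=(4.9, 1.6),
        ka_R=(0.03, 0.02), ka_S=(0.01, 0.009),
        F_R=(1.104, 0.552), F_S=(0.866, 0.258),
        gfr=(3.5, 0.7), erpf=(16.0, 3.2),
    ),
    "6-7mo": GroupSpec(
        bw_kg=(138.0, 8.0),
        V_R=(139.5, 33.1), Cl_R=(3.2, 2.2), Cl_RtoS=(1.6, 0.6),
        V_S=(137.3, 36.0), Cl_S=(2.1, 0.5),
        ka_R=(0.1, 0.1), ka_S=(0.01, 0.009),
        F_R=(1.022, 0.461), F_S=(0.793, 0.437),
        gfr=(1.8, 0.36), erpf=(7.0, 1.4),
    ),
}


@dataclass(frozen=True)
class ErrorModel:
    """Combined proportional + additive residual error with LOQ censoring."""

    proportional_sd: float = 0.10
    additive_sd: float = 0.05
    loq: float = LOQ_UG_PER_ML
    lod_r: float = 0.128  # metadata only
    lod_s: float = 0.165

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValidationError("error SDs must be >= 0")

    def apply(self, rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, float)
        noisy = conc * (1.0 + rng.normal(0.0, self.proportional_sd, conc.shape))
        noisy = noisy + rng.normal(0.0, self.additive_sd, conc.shape)
        return np.maximum(noisy, 0.0)


@dataclass(frozen=True)
class SamplingSchedule:
    """Named sampling grids (minutes after the relevant dose)."""

    iv: tuple[float, ...] = (
        0, 5, 10, 20, 30, 45, 60, 90, 120, 150, 180, 240, 360, 480, 1440
    )
    oral_rich: tuple[float, ...] = (
        0, 5, 10, 20, 30, 45, 60, 75, 90, 105, 120, 150, 180, 240, 360
    )
    oral_sparse: tuple[float, ...] = (0, 30)
    marker: tuple[float, ...] = (0, 5, 10, 30, 60, 120, 180, 360, 480)

    def __post_init__(self) -> None:
        for name in ("iv", "oral_rich", "oral_sparse", "marker"):
            g = np.asarray(getattr(self, name), float)
            if np.any(g < 0) or np.any(np.diff(g) <= 0):
                raise ValidationError(f"{name} grid must be non-negative and increasing")


@dataclass(frozen=True)
class CohortSpec:
    """Full design of a virtual study."""

    groups: dict = field(default_factory=lambda: dict(TABLE2_GROUPS))
    n_per_group: int = 8
    dose_racemic: float = 5.0  # mg/kg, IV and oral
    regimen: Regimen = field(default_factory=Regimen.study_oral)
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    error: ErrorModel = field(default_factory=ErrorModel)
    include_markers: bool = True
    marker_v1: float = 180.0  # iohexol central volume, mL/kg
    marker_v2: float = 120.0
    marker_cld: float = 5.0
    pah_v: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Log-normal draws with arithmetic mean/SD matched by moments."""
    if sd == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def draw_subjects(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw individual subjects (parameters + covariates) for every group.

    All parameters are independent log-normals except the inversion
    clearance, which is drawn as Cl_R times an inversion fraction so the
    structural constraint Cl_RtoS <= Cl_R holds for every subject while
    the Cl_RtoS mean stays exact (see the methods note).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    sid = 0
    for group, g in spec.groups.items():
        n = spec.n_per_group
        draws = {
            name: _lognormal(rng, *getattr(g, name), n)
            for name in ("bw_kg", "V_R", "Cl_R", "V_S", "Cl_S",
                         "ka_R", "ka_S", "F_R", "F_S", "gfr", "erpf")
        }
        m_r, s_r = g.Cl_R
        m_rs, s_rs = g.Cl_RtoS
        mf = m_rs / m_r
        cv_f2 = max((1.0 + (s_rs / m_rs) ** 2) / (1.0 + (s_r / m_r) ** 2) - 1.0, 0.0)
        frac = _lognormal(rng, mf, mf * math.sqrt(cv_f2), n)
        cl_rtos = np.minimum(frac, 1.0) * draws["Cl_R"]
        for i in range(n):
            sid += 1
            rows.append(
                {
                    "subject_id": f"pig{sid:03d}",
                    "age_group": group,
                    "sex": "M" if i < (n + 1) // 2 else "F",
                    **{k: draws[k][i] for k in draws},
                    "Cl_RtoS": cl_rtos[i],
                }
            )
    return pd.DataFrame(rows)


def _subject_params(row) -> EnantiomerParams:
    return EnantiomerParams(
        V_R=row["V_R"], Cl_R=row["Cl_R"], Cl_RtoS=row["Cl_RtoS"],
        V_S=row["V_S"], Cl_S=row["Cl_S"],
        ka_R=row["ka_R"], ka_S=row["ka_S"], F_R=row["F_R"], F_S=row["F_S"],
    )


def _records(rng, spec, row, occasion, analyte, times, conc, dose_number=1):
    noisy = spec.error.apply(rng, conc)
    blq = noisy < spec.error.loq
    return pd.DataFrame(
        {
            "subject_id": row["subject_id"],
            "age_group": row["age_group"],
            "sex": row["sex"],
            "bw_kg": row["bw_kg"],
            "occasion": occasion,
            "dose_number": dose_number,
            "analyte": analyte,
            "time_min": np.asarray(times, float),
            "conc_ug_per_ml": noisy,
            "blq_flag": blq,
        }
    )


def simulate_cohort(
    subjects: pd.DataFrame, spec: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the full study for every drawn subject.

    Emits a long-format table (one row per sample) with dose-relative
    ``time_min``; the pre-dose sample of each occasion is recorded at
    t=0 with zero drug on board (IV/markers) or the superposed trough
    (13th oral dose).  Residual error is applied to every observation and
    BLQ status assigned below the LOQ.
    """
    rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
    sched = spec.schedule
    frames = []
    oral_dose = DoseEvent(0.0, "oral", spec.dose_racemic)
    iv_dose = DoseEvent(0.0, "iv", spec.dose_racemic)
    for _, row in subjects.iterrows():
        p = _subject_params(row)

        # IV day: pre-dose sample is drug-free, model curve afterwards
        t_iv = np.asarray(sched.iv, float)
        cr, cs = simulate_iv_bolus(p, iv_dose, t_iv)
        conc_r, conc_s = cr.concentrations.copy(), cs.concentrations.copy()
        if t_iv[0] == 0:
            conc_r[0] = 0.0
            conc_s[0] = 0.0
        frames.append(_records(rng, spec, row, "iv", "R", t_iv, conc_r))
        frames.append(_records(rng, spec, row, "iv", "S", t_iv, conc_s))

        # oral dose 1 (fasted, rich grid)
        t_po = np.asarray(sched.oral_rich, float)
        cr, cs = simulate_oral(p, oral_dose, t_po)
        frames.append(_records(rng, spec, row, "po_dose1", "R", t_po, cr.concentrations))
        frames.append(_records(rng, spec, row, "po_dose1", "S", t_po, cs.concentrations))

        # oral dose 13 (fed, rich grid) under full superposition
        t13 = spec.regimen.dose_time(13)
        cr, cs = simulate_regimen(p, spec.regimen, t13 + t_po)
        frames.append(_records(rng, spec, row, "po_dose13", "R", t_po, cr.concentrations, 13))
        frames.append(_records(rng, spec, row, "po_dose13", "S", t_po, cs.concentrations, 13))

        # trough + 30 min samples around every other dose
        for d in range(2, len(spec.regimen) + 1):
            if d in (1, 13):
                continue
            td = spec.regimen.dose_time(d)
            t_abs = td + np.asarray(sched.oral_sparse, float)
            cr, cs = simulate_regimen(p, spec.regimen, t_abs)
            frames.append(
                _records(rng, spec, row, "po_sparse", "R", sched.oral_sparse,
                         cr.concentrations, d)
            )
            frames.append(
                _records(rng, spec, row, "po_sparse", "S", sched.oral_sparse,
                         cs.concentrations, d)
            )

        if spec.include_markers:
            t_m = np.asarray(sched.marker, float)
            two_cpt = TwoCompartmentParams(
                V1=spec.marker_v1, Cl=row["gfr"], Cl_d=spec.marker_cld, V2=spec.marker_v2
            )
            io_curve = two_compartment_curve(two_cpt, IOHEXOL_DOSE_MG_PER_KG, t_m)
            conc_io = io_curve.concentrations.copy()
            ke = row["erpf"] / spec.pah_v
            conc_pah = PAH_DOSE_MG_PER_KG * 1000.0 / spec.pah_v * np.exp(-ke * t_m)
            if t_m[0] == 0:
                conc_io[0] = 0.0
                conc_pah[0] = 0.0
            for occ in ("marker_day1", "marker_day2"):
                frames.append(_records(rng, spec, row, occ, "iohexol", t_m, conc_io))
                frames.append(_records(rng, spec, row, occ, "pah", t_m, conc_pah))

    return pd.concat(frames, ignore_index=True)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw subjects and simulate their study data.

    Returns ``(subjects, records)``; all randomness derives from ``seed``
    (default: the spec's own seed).
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_draw, s_sim = root.spawn(2)
    subjects = draw_subjects(spec, seed=s_draw)
    records = simulate_cohort(subjects, spec, seed=s_sim)
    return subjects, records


def derive_total_records(records: pd.DataFrame, loq: float = LOQ_UG_PER_ML) -> pd.DataFrame:
    """Total-drug rows as the pointwise sum of measured R and S.

    Computed only where both enantiomers are quantifiable, mirroring the
    analysis convention that sub-LOQ values never enter downstream sums.
    """
    enant = records[records["analyte"].isin(["R", "S"]) & ~records["blq_flag"]]
    keys = ["subject_id", "age_group", "sex", "bw_kg", "occasion", "dose_number", "time_min"]
    wide = enant.pivot_table(
        index=keys, columns="analyte", values="conc_ug_per_ml", aggfunc="first"
    ).reset_index()
    wide = wide.dropna(subset=["R", "S"])
    total = wide[keys].copy()
    total["analyte"] = "total"
    total["conc_ug_per_ml"] = wide["R"] + wide["S"]
    total["blq_flag"] = total["conc_ug_per_ml"] < loq
    cols = keys[:-1] + ["analyte", "time_min", "conc_ug_per_ml", "blq_flag"]
    return total[cols].sort_values(keys).reset_index(drop=True)


def make_study_config() -> dict:
    """The default four-group study design as a plain serializable mapping."""
    regimen = Regimen.study_oral()
    sched = SamplingSchedule()
    return {
        "age_groups": list(AGE_GROUPS),
        "n_per_group": 8,
        "sex_split": {"M": 4, "F": 4},
        "dose_racemic_mg_per_kg": 5.0,
        "dose_per_enantiomer_mg_per_kg": 2.5,
        "iv": {"route": "iv", "n_doses": 1},
        "oral": {
            "route": "oral",
            "n_doses": len(regimen),
            "times_min": [d.time for d in regimen],
            "within_day_offsets_min": [0, 360, 720],
            "n_days": 5,
            "dose13_time_min": regimen.dose_time(13),
        },
        "sampling": {
            "iv": list(sched.iv),
            "oral_rich": list(sched.oral_rich),
            "oral_sparse": list(sched.oral_sparse),
            "marker": list(sched.marker),
        },
        "loq_ug_per_ml": LOQ_UG_PER_ML,
        "markers": {
            "iohexol_dose_mg_per_kg": IOHEXOL_DOSE_MG_PER_KG,
            "pah_dose_mg_per_kg": PAH_DOSE_MG_PER_KG,
        },
        "bw_kg": {g: list(TABLE2_GROUPS[g].bw_kg) for g in AGE_GROUPS},
    }
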