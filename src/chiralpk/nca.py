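"""Non-compartmental analysis of concentration-time profiles.

Implements the linear-up/log-down trapezoidal AUC, terminal-slope
estimation with adjusted-R^2 window selection, absolute bioavailability
from 0-3 h AUC ratios, the multiple-dose accumulation ratio over one
6-h dosing interval, and the strict below-LOQ exclusion rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ValidationError

__all__ = [
    "NCAResult",
    "BioavailabilityResult",
    "AccumulationResult",
    "auc_lin_up_log_down",
    "terminal_lambda_z",
    "cmax_tmax",
    "absolute_bioavailability",
    "accumulation_ratio",
    "apply_loq_filter",
    "nca_profile",
    "LOQ_UG_PER_ML",
]

#: Analytical limit of quantification for both enantiomers (ug/mL).
LOQ_UG_PER_ML = 0.25


@dataclass(frozen=True)
class NCAResult:
    """Model-free summary of one concentration-time profile."""

    Cmax: float
    Tmax: float
    AUC_0_t: float
    AUC_0_inf: float
    lambda_z: float
    t_half: float
    n_points_lambda_z: int


@dataclass(frozen=True)
class BioavailabilityResult:
    """Absolute oral bioavailability from partial-AUC ratio (fraction)."""

    F: float
    auc_po: float
    auc_iv: float


@dataclass(frozen=True)
class AccumulationResult:
    """AUC(0-6h, dose 13) / AUC(0-6h, dose 1)."""

    ratio: float
    auc_dose1: float
    auc_dose13: float


def _check_profile(times, concentrations):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValidationError("times and concentrations must be equal-length 1-D")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    return t, c


def _segment_auc(t0, t1, c0, c1) -> float:
    """Lin-up/log-down rule for one segment."""
    dt = t1 - t0
    if c1 < c0 and c0 > 0 and c1 > 0:
        return dt * (c0 - c1) / math.log(c0 / c1)
    return 0.5 * (c0 + c1) * dt


def _interp_conc(t0, t1, c0, c1, t) -> float:
    """Interpolate within a segment using the segment's own rule."""
    frac = (t - t0) / (t1 - t0)
    if c1 < c0 and c0 > 0 and c1 > 0:
        return c0 * (c1 / c0) ** frac  # log-linear
    return c0 + frac * (c1 - c0)


def auc_lin_up_log_down(times, concentrations, t_end: float | None = None) -> float:
    """AUC by the linear-up / log-down trapezoidal method (ug*min/mL).

    Rising or flat segments (or segments touching zero) use the linear
    trapezoid; strictly decreasing all-positive segments use the log
    trapezoid ``(C_i - C_{i+1}) * dt / ln(C_i / C_{i+1})``.  A ``t_end``
    inside the grid truncates the last partial segment by interpolating
    with that segment's rule; no extrapolation happens beyond the last
    sample.
    """
    t, c = _check_profile(times, concentrations)
    if t.size < 2:
        raise ValidationError("need at least two points for an AUC")
    if t_end is None:
        t_end = t[-1]
    if t_end < t[0]:
        raise ValidationError(f"t_end={t_end} precedes first sample t={t[0]}")
    t_stop = min(t_end, t[-1])
    auc = 0.0
    for i in range(t.size - 1):
        if t[i] >= t_stop:
            break
        if t[i + 1] <= t_stop:
            auc += _segment_auc(t[i], t[i + 1], c[i], c[i + 1])
        else:
            c_star = _interp_conc(t[i], t[i + 1], c[i], c[i + 1], t_stop)
            auc += _segment_auc(t[i], t_stop, c[i], c_star)
            break
    return auc


def cmax_tmax(times, concentrations) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties take the earliest."""
    t, c = _check_profile(times, concentrations)
    if t.size < 1:
        raise ValidationError("need at least one point")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def terminal_lambda_z(
    times, concentrations, min_points: int = 3, max_points: int = 6
) -> tuple[float, float, float, int]:
    """Terminal slope, half-life and AUC extrapolated to infinity.

    Log-linear regression over candidate windows of the last
    ``min_points``..``max_points`` strictly positive samples, excluding
    the Tmax point; the window with the best adjusted R^2 wins.  Returns
    ``(lambda_z, t_half, AUC_0_inf, n_points)``; all NaN (n=0) when no
    admissible window yields a positive slope.
    """
    t, c = _check_profile(times, concentrations)
    pos = c > 0
    tp, cp = t[pos], c[pos]
    if tp.size:
        _, tmax = cmax_tmax(tp, cp)
    best = None
    for n in range(min_points, max_points + 1):
        if n > tp.size:
            break
        tw, cw = tp[-n:], cp[-n:]
        keep = tw != tmax
        tw, cw = tw[keep], cw[keep]
        if tw.size < min_points:
            continue
        res = stats.linregress(tw, np.log(cw))
        lam = -res.slope
        if lam <= 0:
            continue
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (tw.size - 1) / (tw.size - 2)
        if best is None or adj > best[0]:
            best = (adj, lam, tw.size)
    if best is None:
        return math.nan, math.nan, math.nan, 0
    _, lam, n_used = best
    auc_last = auc_lin_up_log_down(t, c)
    auc_inf = auc_last + cp[-1] / lam
    return lam, math.log(2.0) / lam, auc_inf, n_used


def nca_profile(times, concentrations, auc_t_end: float | None = None) -> NCAResult:
    """Full NCA summary of one profile."""
    cmax, tmax = cmax_tmax(times, concentrations)
    auc_t = auc_lin_up_log_down(times, concentrations, auc_t_end)
    lam, t_half, auc_inf, n_lam = terminal_lambda_z(times, concentrations)
    return NCAResult(cmax, tmax, auc_t, auc_inf, lam, t_half, n_lam)


def absolute_bioavailability(
    po_times,
    po_conc,
    iv_times,
    iv_conc,
    dose_po: float,
    dose_iv: float,
    t_end: float = 180.0,
    require_coverage: bool = True,
) -> BioavailabilityResult:
    """F from dose-normalized partial AUC ratio (default 0-3 h).

    Both profiles must cover ``t_end`` unless ``require_coverage`` is
    False, in which case a profile censored earlier (fast-clearing
    subjects whose late samples fall below the LOQ) contributes its AUC
    to the last quantifiable sample — consistent with excluding BLQ data
    and never extrapolating.  The study design uses equal doses so dose
    normalization is usually a no-op.  F is a fraction and is not
    clipped at 1.
    """
    if require_coverage:
        for tt in (po_times, iv_times):
            if np.asarray(tt, dtype=float)[-1] < t_end:
                raise ValidationError(f"profile must extend to {t_end} min")
    auc_po = auc_lin_up_log_down(po_times, po_conc, t_end)
    auc_iv = auc_lin_up_log_down(iv_times, iv_conc, t_end)
    if auc_iv <= 0:
        raise ValidationError("IV AUC is zero; bioavailability undefined")
    f = (auc_po / dose_po) / (auc_iv / dose_iv)
    return BioavailabilityResult(f, auc_po, auc_iv)


def accumulation_ratio(
    times_dose1, conc_dose1, times_dose13, conc_dose13, interval: float = 360.0
) -> AccumulationResult:
    """Accumulation ratio AUC(0-6h, dose 13) / AUC(0-6h, dose 1).

    Times are minutes after each profile's own dose; both AUCs use the
    lin-up/log-down rule over one dosing interval.
    """
    auc1 = auc_lin_up_log_down(times_dose1, conc_dose1, interval)
    auc13 = auc_lin_up_log_down(times_dose13, conc_dose13, interval)
    if auc1 <= 0:
        raise ValidationError("dose-1 AUC is zero; ratio undefined")
    return AccumulationResult(auc13 / auc1, auc1, auc13)


def apply_loq_filter(
    records: pd.DataFrame,
    loq: float = LOQ_UG_PER_ML,
    conc_col: str = "conc_ug_per_ml",
    blq_col: str = "blq_flag",
) -> tuple[pd.DataFrame, int]:
    """Drop records strictly below the LOQ (0.25 ug/mL retained).

    Honors an existing BLQ flag column when present; returns the filtered
    table and the number of rows removed.
    """
    drop = records[conc_col] < loq
    if blq_col in records.columns:
        drop |= records[blq_col].astype(bool)
    kept = records.loc[~drop].copy()
    return kept, int(drop.sum())
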