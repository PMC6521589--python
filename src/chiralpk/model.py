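"""Two-enantiomer one-compartment model with systemic chiral inversion.

The structural model treats each enantiomer of a racemic drug (here
ibuprofen) as a one-compartment system, with a unidirectional inversion
clearance carrying the R-enantiomer into the S-compartment:

    dA_R/dt = in_R(t) - (Cl_R / V_R) * A_R
    dA_S/dt = in_S(t) + (Cl_RtoS / V_R) * A_R - (Cl_S / V_S) * A_S

where ``A`` are amounts per kg body weight, ``Cl_R`` is the *total*
clearance of R (inversion included, so irreversible loss from R by other
routes is ``Cl_R - Cl_RtoS``), and ``in`` is the dosing input (bolus or a
first-order depot for oral dosing).  Each enantiomer receives half of the
racemic dose.

All solutions are closed-form sums of ``t**p * exp(-k t)`` terms; a stiff
numerical integrator over the same ODEs is provided as an independent
oracle.  Units package-wide: minutes, mL/kg, mL/(min*kg), ug/mL, doses in
mg/kg (converted to ug/kg internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "EnantiomerParams",
    "DoseEvent",
    "Regimen",
    "ConcentrationCurve",
    "ValidationError",
    "simulate_iv_bolus",
    "simulate_oral",
    "simulate_regimen",
    "total_curve",
    "ode_regimen",
    "DEGENERATE_RATE_TOL",
]

#: Rate constants closer than this (1/min) are treated as equal and the
#: limiting t*exp(-kt) solution is used instead of the generic form.
DEGENERATE_RATE_TOL = 1e-9

MG_PER_KG_TO_UG_PER_KG = 1000.0


class ValidationError(ValueError):
    """Raised when inputs violate a model contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnantiomerParams:
    """Structural parameters of the two-enantiomer inversion model.

    Parameters
    ----------
    V_R, V_S
        Apparent distribution volumes (mL/kg).
    Cl_R
        Total clearance of R including the inversion route (mL/(min*kg)).
    Cl_RtoS
        Systemic inversion clearance R -> S (mL/(min*kg)); a component of
        ``Cl_R``, so ``0 <= Cl_RtoS <= Cl_R``.
    Cl_S
        Total clearance of S (mL/(min*kg)).
    ka_R, ka_S
        First-order absorption rate constants (1/min); required for oral
        simulation only.
    F_R, F_S
        Absolute oral bioavailability fractions; may exceed 1 when
        estimated from data and are never clipped.
    """

    V_R: float
    Cl_R: float
    Cl_RtoS: float
    V_S: float
    Cl_S: float
    ka_R: float | None = None
    ka_S: float | None = None
    F_R: float | None = None
    F_S: float | None = None

    def __post_init__(self) -> None:
        for name in ("V_R", "Cl_R", "V_S", "Cl_S"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive, got {v!r}")
        if not (0.0 <= self.Cl_RtoS <= self.Cl_R):
            raise ValidationError(
                f"Cl_RtoS must lie in [0, Cl_R]={self.Cl_R}, got {self.Cl_RtoS}"
            )
        for name in ("ka_R", "ka_S", "F_R", "F_S"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be non-negative, got {v!r}")

    @classmethod
    def from_additive_convention(
        cls, *, V_R: float, Cl_R_other: float, Cl_RtoS: float, **kw
    ) -> "EnantiomerParams":
        """Alternative convention: ``Cl_R_other`` excludes inversion.

        Total R clearance is then ``Cl_R_other + Cl_RtoS``.  Provided for
        sensitivity analysis; the package default treats reported Cl_R as
        total (inversion-inclusive).
        """
        return cls(V_R=V_R, Cl_R=Cl_R_other + Cl_RtoS, Cl_RtoS=Cl_RtoS, **kw)

    def require_oral(self) -> None:
        for name in ("ka_R", "ka_S", "F_R", "F_S"):
            if getattr(self, name) is None:
                raise ValidationError(f"oral simulation requires {name}")
        for name in ("ka_R", "ka_S"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0 for oral simulation")


@dataclass(frozen=True)
class DoseEvent:
    """One administration of the racemate.

    ``amount_racemic`` is the racemic dose in mg/kg; each enantiomer
    receives half of it.  ``fed`` is metadata only.
    """

    time: float
    route: str  # "iv" | "oral"
    amount_racemic: float
    fed: bool = False

    def __post_init__(self) -> None:
        if self.route not in ("iv", "oral"):
            raise ValidationError(f"route must be 'iv' or 'oral', got {self.route!r}")
        if not self.amount_racemic > 0:
            raise ValidationError("amount_racemic must be > 0")
        if self.time < 0:
            raise ValidationError("dose time must be >= 0")

    @property
    def enantiomer_dose_ug(self) -> float:
        """Per-enantiomer dose, ug/kg (half the racemic mg/kg dose)."""
        return 0.5 * self.amount_racemic * MG_PER_KG_TO_UG_PER_KG


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events."""

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if not self.doses:
            raise ValidationError("regimen needs at least one dose")
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("dose times must be non-decreasing")

    def __iter__(self):
        return iter(self.doses)

    def __len__(self) -> int:
        return len(self.doses)

    @classmethod
    def single_iv(cls, amount_racemic: float = 5.0) -> "Regimen":
        return cls((DoseEvent(0.0, "iv", amount_racemic),))

    @classmethod
    def study_oral(
        cls,
        amount_racemic: float = 5.0,
        offsets: Sequence[float] = (0.0, 360.0, 720.0),
        n_days: int = 5,
        day_length: float = 1440.0,
    ) -> "Regimen":
        """The study's t.i.d. x 5 days oral regimen.

        Three daily doses 6 h apart (12 h overnight gap), so dose 13 falls
        at 5760 min after the first oral dose.  Only the first dose is
        given fasted.
        """
        doses = []
        for day in range(n_days):
            for i, off in enumerate(offsets):
                fed = not (day == 0 and i == 0)
                doses.append(
                    DoseEvent(day * day_length + off, "oral", amount_racemic, fed=fed)
                )
        return cls(tuple(doses))

    def dose_time(self, index: int) -> float:
        """Time of the 1-based ``index``-th dose."""
        return self.doses[index - 1].time


@dataclass(frozen=True)
class ConcentrationCurve:
    """A plasma concentration-time profile for one analyte."""

    analyte: str  # "R" | "S" | "total" | marker names
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        if self.times.shape != self.concentrations.shape:
            raise ValidationError("times and concentrations must have equal shape")
        if np.any(self.concentrations < -1e-12):
            raise ValidationError("concentrations must be >= 0")


def total_curve(curve_r: ConcentrationCurve, curve_s: ConcentrationCurve) -> ConcentrationCurve:
    """Pointwise sum of the enantiomer curves (total drug)."""
    if curve_r.times.shape != curve_s.times.shape or not np.array_equal(
        curve_r.times, curve_s.times
    ):
        raise ValidationError("curves must share the same time grid")
    return ConcentrationCurve(
        "total", curve_r.times, curve_r.concentrations + curve_s.concentrations
    )


# ---------------------------------------------------------------------------
# exponential-sum algebra
#
# Every solution of the linear model is a finite sum of c * t**p * exp(-a t)
# terms.  _convolve pushes such a term through a first-order compartment
# with elimination rate k (response to y' = input - k*y, y(0)=0), staying
# in closed form; coincident rates collapse to the polynomial-lifted term.
# ---------------------------------------------------------------------------

Term = tuple[float, float, int]  # (coef, rate, power)


def _convolve(term: Term, k: float) -> list[Term]:
    c, a, p = term
    if abs(a - k) <= DEGENERATE_RATE_TOL:
        return [(c / (p + 1), k, p + 1)]
    d = a - k
    # R_p = e^{-kt} * I_p(t; d) with I_p = \int_0^t s^p e^{-d s} ds obeying
    # I_p = (p I_{p-1} - t^p e^{-d t}) / d
    terms: list[Term] = [(1.0 / d, k, 0), (-1.0 / d, a, 0)]
    for q in range(1, p + 1):
        terms = [(co * q / d, r, pw) for co, r, pw in terms]
        terms.append((-1.0 / d, a, q))
    return [(c * co, r, pw) for co, r, pw in terms]


def _eval_terms(terms: Iterable[Term], t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c, a, p in terms:
        out += c * t**p * np.exp(-a * t)
    return out


def _integral_terms(terms: Iterable[Term], t_end: float) -> float:
    """Exact integral over [0, t_end] of a term sum."""
    total = 0.0
    for c, a, p in terms:
        if abs(a) <= DEGENERATE_RATE_TOL:
            total += c * t_end ** (p + 1) / (p + 1)
            continue
        # recursion I_p = (p I_{p-1} - t^p e^{-a t}) / a
        ip = (1.0 - math.exp(-a * t_end)) / a
        for q in range(1, p + 1):
            ip = (q * ip - t_end**q * math.exp(-a * t_end)) / a
        total += c * ip
    return total


def _iv_terms(params: EnantiomerParams, dose: DoseEvent) -> tuple[list[Term], list[Term]]:
    """Closed-form amount terms (ug/kg) after one IV bolus at t=0."""
    d2 = dose.enantiomer_dose_ug
    k_r = params.Cl_R / params.V_R
    k_s = params.Cl_S / params.V_S
    k_rs = params.Cl_RtoS / params.V_R
    a_r: list[Term] = [(d2, k_r, 0)]
    a_s: list[Term] = [(d2, k_s, 0)]
    for c, a, p in a_r:
        a_s.extend(_convolve((k_rs * c, a, p), k_s))
    return a_r, a_s


def _oral_terms(params: EnantiomerParams, dose: DoseEvent) -> tuple[list[Term], list[Term]]:
    """Closed-form amount terms after one oral dose at t=0 (first-order depot)."""
    params.require_oral()
    d2 = dose.enantiomer_dose_ug
    k_r = params.Cl_R / params.V_R
    k_s = params.Cl_S / params.V_S
    k_rs = params.Cl_RtoS / params.V_R
    a_r = _convolve((params.ka_R * params.F_R * d2, params.ka_R, 0), k_r)
    a_s = _convolve((params.ka_S * params.F_S * d2, params.ka_S, 0), k_s)
    for c, a, p in a_r:
        a_s.extend(_convolve((k_rs * c, a, p), k_s))
    return a_r, a_s


def _dose_terms(params: EnantiomerParams, dose: DoseEvent):
    return _iv_terms(params, dose) if dose.route == "iv" else _oral_terms(params, dose)


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------


def _as_curves(params, a_r, a_s, times, tshift=0.0):
    times = np.asarray(times, dtype=float)
    tau = times - tshift
    mask = tau >= 0
    c_r = np.zeros_like(times)
    c_s = np.zeros_like(times)
    c_r[mask] = _eval_terms(a_r, tau[mask]) / params.V_R
    c_s[mask] = _eval_terms(a_s, tau[mask]) / params.V_S
    return c_r, c_s


def simulate_iv_bolus(
    params: EnantiomerParams, dose: DoseEvent, times: Sequence[float]
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Closed-form enantiomer curves after a single IV bolus.

    The R curve is mono-exponential; the S curve is bi-exponential (its own
    elimination plus the inversion input from R).  ``times`` are minutes
    since the dose event's own time.
    """
    if dose.route != "iv":
        raise ValidationError("simulate_iv_bolus requires an IV dose event")
    a_r, a_s = _iv_terms(params, dose)
    c_r, c_s = _as_curves(params, a_r, a_s, times)
    return (
        ConcentrationCurve("R", times, c_r),
        ConcentrationCurve("S", times, c_s),
    )


def simulate_oral(
    params: EnantiomerParams, dose: DoseEvent, times: Sequence[float]
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Closed-form enantiomer curves after a single oral dose."""
    if dose.route != "oral":
        raise ValidationError("simulate_oral requires an oral dose event")
    if params.F_R == 0 and params.F_S == 0:
        z = np.zeros(len(np.atleast_1d(times)))
        return ConcentrationCurve("R", times, z), ConcentrationCurve("S", times, z.copy())
    a_r, a_s = _oral_terms(params, dose)
    c_r, c_s = _as_curves(params, a_r, a_s, times)
    return (
        ConcentrationCurve("R", times, c_r),
        ConcentrationCurve("S", times, c_s),
    )


def simulate_regimen(
    params: EnantiomerParams, regimen: Regimen, times: Sequence[float]
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Superpose single-dose solutions over all dose events.

    The model is linear, so the multi-dose solution is the sum of shifted
    single-dose solutions; times before the first dose yield zero.
    """
    times = np.asarray(times, dtype=float)
    c_r = np.zeros_like(times)
    c_s = np.zeros_like(times)
    for dose in regimen:
        a_r, a_s = _dose_terms(params, dose)
        dr, ds = _as_curves(params, a_r, a_s, times, tshift=dose.time)
        c_r += dr
        c_s += ds
    return (
        ConcentrationCurve("R", times, c_r),
        ConcentrationCurve("S", times, c_s),
    )


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------


def ode_regimen(
    params: EnantiomerParams,
    regimen: Regimen | DoseEvent,
    times: Sequence[float],
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Stiff numerical integration of the full depot+central ODE system.

    Independent oracle for the closed-form solutions: integrates
    (depot_R, A_R, depot_S, A_S) piecewise between dose events with
    ``scipy.integrate.solve_ivp`` (LSODA).
    """
    if isinstance(regimen, DoseEvent):
        regimen = Regimen((regimen,))
    times = np.asarray(times, dtype=float)
    k_r = params.Cl_R / params.V_R
    k_s = params.Cl_S / params.V_S
    k_rs = params.Cl_RtoS / params.V_R
    ka_r = params.ka_R or 0.0
    ka_s = params.ka_S or 0.0

    def rhs(t, y):
        dep_r, a_r, dep_s, a_s = y
        return [
            -ka_r * dep_r,
            ka_r * dep_r - k_r * a_r,
            -ka_s * dep_s,
            ka_s * dep_s + k_rs * a_r - k_s * a_s,
        ]

    out_r = np.zeros_like(times)
    out_s = np.zeros_like(times)
    state = np.zeros(4)
    dose_times = [d.time for d in regimen]
    boundaries = dose_times + [max(times.max(), dose_times[-1]) + 1.0]
    # times strictly before the first dose stay zero
    for i, dose in enumerate(regimen):
        state = state.copy()
        d2 = dose.enantiomer_dose_ug
        if dose.route == "iv":
            state[1] += d2
            state[3] += d2
        else:
            params.require_oral()
            state[0] += params.F_R * d2
            state[2] += params.F_S * d2
        t0, t1 = dose.time, boundaries[i + 1]
        sel = (times >= t0) & (times <= t1)
        t_eval = times[sel]
        span_end = max(t1, t_eval.max() if t_eval.size else t1)
        if span_end > t0:
            sol = solve_ivp(
                rhs,
                (t0, span_end),
                state,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                dense_output=True,
            )
            if t_eval.size:
                y = sol.sol(t_eval)
                out_r[sel] = y[1] / params.V_R
                out_s[sel] = y[3] / params.V_S
            state = sol.sol(t1) if t1 <= span_end else sol.y[:, -1]
    return (
        ConcentrationCurve("R", times, np.maximum(out_r, 0.0)),
        ConcentrationCurve("S", times, np.maximum(out_s, 0.0)),
    )


def eliminated_amount(params: EnantiomerParams, dose: DoseEvent, t_end: float) -> float:
    """Cumulative irreversibly eliminated amount (ug/kg) after one dose.

    Exact quadrature of ``Cl_S*C_S + (Cl_R - Cl_RtoS)*C_R`` over [0, t_end];
    used by the mass-balance checks.
    """
    a_r, a_s = _dose_terms(params, dose)
    int_cr = _integral_terms(a_r, t_end) / params.V_R
    int_cs = _integral_terms(a_s, t_end) / params.V_S
    return (params.Cl_R - params.Cl_RtoS) * int_cr + params.Cl_S * int_cs
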