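"""Allometric (power-law) scaling of PK parameters.

Relates whole-body clearance or distribution volume to body weight (or to
renal markers such as GFR/eRPF) through ``Y = a * X**b``; the exponent b
is the allometric coefficient, obtained by ordinary least squares of
ln(Y) on ln(X).  Both group-mean and individual-subject regressions are
supported; per-kg parameters are converted to whole-body values by
multiplying by body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ValidationError

__all__ = ["AllometricFit", "fit_power_law", "whole_body", "STUDY_MEAN_BW_KG"]

#: Mean body weights (kg) of the four study age groups; the oldest group
#: default is the mid-point of the reported male (134 kg) and female
#: (142 kg) sub-cohorts.
STUDY_MEAN_BW_KG = {"1wk": 3.0, "4wk": 7.0, "8wk": 20.1, "6-7mo": 138.0}


@dataclass(frozen=True)
class AllometricFit:
    """Power-law fit Y = a * X**b on log-log axes."""

    exponent: float
    intercept_ln: float
    r: float
    n: int
    two_point: bool = False

    @property
    def coefficient(self) -> float:
        """Multiplier a = exp(intercept)."""
        return math.exp(self.intercept_ln)

    def predict(self, x) -> np.ndarray:
        return self.coefficient * np.asarray(x, float) ** self.exponent


def fit_power_law(x, y) -> AllometricFit:
    """OLS of ln(y) on ln(x); the slope is the allometric exponent.

    Requires strictly positive inputs of equal length; two points give an
    exact (flagged) fit, three or more a regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValidationError("need at least two points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("power-law fit requires strictly positive values")
    lx, ly = np.log(x), np.log(y)
    if x.size == 2:
        slope = (ly[1] - ly[0]) / (lx[1] - lx[0])
        return AllometricFit(slope, ly[0] - slope * lx[0], 1.0, 2, two_point=True)
    res = stats.linregress(lx, ly)
    return AllometricFit(res.slope, res.intercept, res.rvalue, int(x.size))


def whole_body(per_kg_values, body_weights_kg) -> np.ndarray:
    """Convert weight-normalized parameters to whole-body values.

    Elementwise product with body weight; units relabel from
    mL/(min*kg) to mL/min (clearances) or mL/kg to mL (volumes).
    """
    v = np.asarray(per_kg_values, dtype=float)
    bw = np.asarray(body_weights_kg, dtype=float)
    if v.shape != bw.shape:
        raise ValidationError("value and body-weight arrays must match in length")
    return v * bw
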