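"""Cross-temperature secondary models.

Two classical summaries of how degradation speed responds to temperature:

* the Arrhenius model, ln k = ln A - Ea/(R T): activation energy Ea from the
  slope of ln k against reciprocal absolute temperature;
* the thermal-death-time model, log10 D linear in temperature: the z-value is
  the temperature rise that divides the decimal reduction time D by ten.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .constants import R, celsius_to_kelvin
from .errors import SingularDesignError, UndefinedResultError, ValidationError


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius regression summary: Ea in kJ/mol, lnA in ln(min^-1)."""

    ea: float
    ea_se: float
    ln_a: float
    r2: float
    n: int


@dataclass(frozen=True)
class ZValueResult:
    """z-value regression summary: z and its delta-method SE in °C."""

    z: float
    z_se: float
    r2: float
    n: int


def _check_points(points: Sequence[tuple[float, float]], what: str) -> tuple[np.ndarray, np.ndarray]:
    pts = list(points)
    if len(pts) < 2:
        raise ValidationError(f"need at least 2 (temperature, {what}) points")
    temp = np.asarray([p[0] for p in pts], dtype=float)
    val = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(val <= 0):
        raise ValidationError(f"all {what} values must be positive")
    if len(np.unique(temp)) < 2:
        raise SingularDesignError("need at least 2 distinct temperatures")
    return temp, val


def arrhenius_fit(points: Iterable[tuple[float, float]]) -> ArrheniusResult:
    """Estimate the activation energy from (temperature °C, k min^-1) pairs.

    OLS of ln k on 1/T_K; Ea = -slope * R / 1000 in kJ/mol, its SE from the
    slope SE, lnA the intercept. The regression is unweighted.

    Examples
    --------
    >>> ks = {75: 0.0069, 95: 0.0138, 115: 0.0253, 135: 0.0737, 155: 0.1865}
    >>> round(arrhenius_fit(ks.items()).ea, 2)
    50.83
    """
    temp_c, k = _check_points(points, "k")
    x = 1.0 / np.array([celsius_to_kelvin(t) for t in temp_c])
    res = stats.linregress(x, np.log(k))
    ea = -res.slope * R / 1000.0
    ea_se = res.stderr * R / 1000.0
    return ArrheniusResult(
        ea=float(ea),
        ea_se=float(ea_se),
        ln_a=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(temp_c),
    )


def z_value_fit(points: Iterable[tuple[float, float]]) -> ZValueResult:
    """Estimate the z-value from (temperature °C, D-value min) pairs.

    OLS of log10 D on temperature; z = -1/slope. The slope is offset-
    invariant, so Celsius and Kelvin give the same z. The SE follows from the
    delta method: se(z) = se(slope) / slope^2.

    Raises
    ------
    UndefinedResultError
        If the fitted slope is zero (D does not change with temperature).
    """
    temp_c, d = _check_points(points, "D")
    res = stats.linregress(temp_c, np.log10(d))
    if res.slope == 0:
        raise UndefinedResultError("z undefined: D does not vary with temperature")
    z = -1.0 / res.slope
    z_se = res.stderr / res.slope**2
    return ZValueResult(z=float(z), z_se=float(z_se), r2=float(res.rvalue**2), n=len(temp_c))


def z_from_arrhenius(ea_kj_mol: float, t_kelvin: float) -> float:
    """Small-range approximation z ≈ ln10 * R * T^2 / Ea (°C).

    Useful as a consistency check between the two secondary models around a
    reference absolute temperature.
    """
    if ea_kj_mol <= 0:
        raise ValidationError("Ea must be positive")
    return math.log(10.0) * R * t_kelvin**2 / (ea_kj_mol * 1000.0)
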