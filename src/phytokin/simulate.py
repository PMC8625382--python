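"""Synthetic measurement generator emulating the heat-treatment study design.

The generators invert the models the analysis assumes, so the whole pipeline
can be exercised and calibrated without any laboratory data:

* first-order decay at the study temperatures (default 75-155 °C, 0-60 min,
  triplicate) with multiplicative lognormal noise — spectrophotometric error
  scales with the signal;
* Arrhenius-consistent rate-constant sets for round-trip recovery tests;
* linear-in-log dose-response tables at the assay concentrations
  (0.5, 1, 5 ug/mL) with additive Gaussian noise on the percentage scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import reference
from .bioassay import DosePoint, DoseResponseSeries
from .constants import R, celsius_to_kelvin
from .errors import ConfigurationError, ValidationError
from .kinetics import DegradationSeries, Observation

#: Default dose-response steepness (% inhibition per log10 concentration):
#: the tangent slope of a unit-Hill logistic at its midpoint, 25*ln(10).
HILL_MIDPOINT_SLOPE = 25.0 * math.log(10.0)


@dataclass(frozen=True)
class DegradationDesign:
    """Sampling design of a heat-treatment experiment.

    Defaults mirror the study design this package targets: five temperatures
    between 75 and 155 °C, sampling at 0-60 min in 15-min steps, triplicate
    tubes, and ~3% multiplicative measurement noise (the relative SDs printed
    for fitted rate constants in comparable studies run 3-12%).
    """

    temperatures: tuple[float, ...] = reference.STUDY_TEMPERATURES
    times: tuple[float, ...] = reference.STUDY_TIMES
    replicates: int = reference.STUDY_REPLICATES
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperatures:
            raise ValidationError("temperatures must be non-empty")
        if list(self.temperatures) != sorted(set(self.temperatures)):
            raise ValidationError("temperatures must be strictly increasing")
        if not self.times or 0.0 not in self.times:
            raise ValidationError("times must include 0")
        if list(self.times) != sorted(set(self.times)) or min(self.times) < 0:
            raise ValidationError("times must be non-negative and strictly increasing")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


@dataclass(frozen=True)
class TrueKinetics:
    """Generating truth: rate constant per temperature and initial response."""

    k_by_temperature: dict[float, float] = field(
        default_factory=lambda: dict(reference.TAC_RATE_CONSTANTS)
    )
    c0: float = 1.0
    analyte: str = "TAC"

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.k_by_temperature.values()):
            raise ValidationError("rate constants must be >= 0")
        if self.c0 <= 0:
            raise ValidationError("c0 must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with median 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_degradation(
    design: DegradationDesign, truth: TrueKinetics
) -> list[DegradationSeries]:
    """Simulate one degradation experiment: a series per design temperature.

    response(t) = c0 * exp(-k t) * eps(t), eps lognormal with median 1 and
    CV = design.noise_cv, independent across tubes and time points.
    Deterministic for a fixed design seed; responses strictly positive.
    """
    missing = [t for t in design.temperatures if t not in truth.k_by_temperature]
    if missing:
        raise ConfigurationError(f"no rate constant for temperatures {missing}")
    rng = np.random.default_rng(design.seed)
    out: list[DegradationSeries] = []
    times = np.asarray(design.times, dtype=float)
    for temp in design.temperatures:
        k = truth.k_by_temperature[temp]
        clean = truth.c0 * np.exp(-k * times)
        obs: list[Observation] = []
        for rep in range(1, design.replicates + 1):
            eps = _lognormal_factors(rng, design.noise_cv, len(times))
            for t, resp in zip(times, clean * eps):
                obs.append(Observation(float(t), float(resp), rep))
        out.append(
            DegradationSeries(
                analyte=truth.analyte, temperature_c=float(temp), observations=obs
            )
        )
    return out


def generate_arrhenius_k(
    ea_kj_mol: float, ln_a: float, temperatures: Iterable[float]
) -> dict[float, float]:
    """Rate constants exactly on an Arrhenius line (for recovery tests).

    k(T) = exp(lnA - Ea*1000/(R*T_K)), T in °C, k in min^-1. Deterministic.
    """
    temps = list(temperatures)
    if not temps:
        raise ValidationError("temperatures must be non-empty")
    if not math.isfinite(ea_kj_mol):
        raise ValidationError("Ea must be finite")
    return {
        float(t): math.exp(ln_a - ea_kj_mol * 1000.0 / (R * celsius_to_kelvin(t)))
        for t in temps
    }


def ln_a_for_k_at(ea_kj_mol: float, temperature_c: float, k: float) -> float:
    """The lnA that puts an Arrhenius line with slope Ea through (T, k)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    return math.log(k) + ea_kj_mol * 1000.0 / (R * celsius_to_kelvin(temperature_c))


def generate_dose_response(
    ic50: float,
    slope: float = HILL_MIDPOINT_SLOPE,
    concentrations: Sequence[float] = reference.ASSAY_CONCENTRATIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    enzyme: str = "enzyme",
) -> DoseResponseSeries:
    """Simulate an inhibition assay on the linear-in-log model.

    inhibition(c) = 50 + slope*(log10 c - log10 ic50) + N(0, noise_sd),
    clipped to [0, 100]. Slope is in percentage points per log10 unit of
    concentration. Reproducible under a fixed seed.
    """
    if ic50 <= 0:
        raise ValidationError("ic50 must be positive")
    if any(c <= 0 for c in concentrations):
        raise ValidationError("concentrations must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    pts: list[DosePoint] = []
    for rep in range(1, replicates + 1):
        for c in concentrations:
            mean = 50.0 + slope * (math.log10(c) - math.log10(ic50))
            value = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            pts.append(DosePoint(float(c), float(np.clip(value, 0.0, 100.0)), rep))
    return DoseResponseSeries(enzyme=enzyme, points=pts)
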