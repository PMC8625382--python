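"""Spectrophotometric quantification: pH-differential anthocyanins,
standard-curve calibration for total phenolics (gallic acid equivalents) and
DPPH antioxidant activity (Trolox equivalents).

The pH-differential method exploits the reversible structural change of
monomeric anthocyanins between pH 1.0 (colored oxonium form) and pH 4.5
(colorless hemiketal): the absorbance difference at 520 nm, corrected for haze
at 700 nm, is proportional to the monomeric pigment content via Beer-Lambert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SingularDesignError, ValidationError

logger = logging.getLogger(__name__)

#: Molar mass of cyanidin-3-O-glucoside (g/mol), the reference anthocyanin.
C3G_MOLAR_MASS = 449.2
#: Molar absorptivity of cyanidin-3-O-glucoside (L/(mol*cm)).
C3G_EPSILON = 26900.0


@dataclass(frozen=True)
class PhDifferentialReading:
    """Absorbance readings of one sample in the two pH buffers.

    a520/a700 at pH 1.0 and pH 4.5 in absorbance units; ``dilution_factor``
    >= 1; ``path_length`` in cm; ``mw`` and ``epsilon`` default to the
    cyanidin-3-O-glucoside constants.
    """

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float
    dilution_factor: float = 1.0
    path_length: float = 1.0
    mw: float = C3G_MOLAR_MASS
    epsilon: float = C3G_EPSILON

    def __post_init__(self) -> None:
        for name in ("a520_ph1", "a700_ph1", "a520_ph45", "a700_ph45"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative absorbance {name}")
        if self.dilution_factor < 1:
            raise ValidationError("dilution factor must be >= 1")
        if self.path_length <= 0:
            raise ValidationError("path length must be positive")

    @property
    def corrected_absorbance(self) -> float:
        """A = (A520 - A700)_pH1 - (A520 - A700)_pH4.5."""
        return (self.a520_ph1 - self.a700_ph1) - (self.a520_ph45 - self.a700_ph45)


@dataclass(frozen=True)
class StandardCurve:
    """Calibration line: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r2: float
    standard: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("calibration slope must be nonzero")


def tac_ph_differential(
    reading: PhDifferentialReading, sample_mass_per_volume: float
) -> float:
    """Total monomeric anthocyanins, mg C3G equivalents per g dry weight.

    Pigment concentration (mg/L) = A * MW * DF * 1000 / (epsilon * path);
    dividing by the sample loading (g DW per L of assayed solution) converts
    to a per-gram basis. A negative corrected absorbance means no monomeric
    anthocyanin signal and yields 0 with a warning.
    """
    if sample_mass_per_volume <= 0:
        raise ValidationError("sample mass per volume must be positive")
    a = reading.corrected_absorbance
    if a < 0:
        logger.warning("negative pH-differential absorbance %.4f; reporting 0", a)
        return 0.0
    mg_per_l = a * reading.mw * reading.dilution_factor * 1000.0 / (
        reading.epsilon * reading.path_length
    )
    return mg_per_l / sample_mass_per_volume


def calibrate_standard(
    points: Iterable[tuple[float, float]], standard: str = ""
) -> StandardCurve:
    """OLS calibration line from (standard concentration, absorbance) pairs."""
    pts = list(points)
    if len(pts) < 3:
        raise InsufficientDataError("calibration needs at least 3 points")
    conc = np.asarray([p[0] for p in pts], dtype=float)
    ab = np.asarray([p[1] for p in pts], dtype=float)
    if len(np.unique(conc)) < 2:
        raise SingularDesignError("calibration needs at least 2 distinct concentrations")
    res = stats.linregress(conc, ab)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        standard=standard,
    )


def quantify_against_curve(
    absorbance: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    sample_mass_per_volume: float = 1.0,
) -> float:
    """Equivalent standard concentration per gram dry weight.

    (absorbance - intercept)/slope, scaled by the dilution factor and divided
    by the sample loading. Negative results are floored at 0 with a warning.
    """
    if dilution_factor < 1:
        raise ValidationError("dilution factor must be >= 1")
    if sample_mass_per_volume <= 0:
        raise ValidationError("sample mass per volume must be positive")
    value = (absorbance - curve.intercept) / curve.slope
    value = value * dilution_factor / sample_mass_per_volume
    if value < 0:
        logger.warning("quantification below 0 (%.4g); reporting 0", value)
        return 0.0
    return value
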