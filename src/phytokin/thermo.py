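"""Activation thermodynamics of thermal degradation (Eyring formalism).

From an activation energy Ea and the per-temperature rate constants k, the
transition-state parameters follow as

    dH = Ea - R*T                    (activation enthalpy, kJ/mol)
    dG = R*T * ln(kB*T / (h*k_s))    (Gibbs free energy of activation, kJ/mol)
    dS = (dH - dG) / T               (activation entropy, J/(mol*K))

with k_s the rate constant in s^-1 and a transmission coefficient of 1.
Positive dH and dG with negative dS are the usual signature of endothermic,
non-spontaneous degradation with an ordered transition state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .constants import H, KB, R, celsius_to_kelvin
from .errors import ValidationError
from .kinetics import FirstOrderFit
from .secondary import ArrheniusResult

#: Rate constants arrive in min^-1 from the kinetic fits; Eyring needs s^-1.
SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class ThermoRow:
    """Activation thermodynamics at one absolute temperature.

    dH and dG in kJ/mol, dS in J/(mol*K); the *_se fields carry first-order
    delta-method standard errors propagated from the replicate SD of k (dH_se
    is the Ea regression SE) and are nan when no uncertainty is available.
    """

    analyte: str
    t_kelvin: float
    dh: float
    dg: float
    ds: float
    dh_se: float = math.nan
    dg_se: float = math.nan
    ds_se: float = math.nan

    def __post_init__(self) -> None:
        # dS*T/1000 == dH - dG must close to machine precision
        assert math.isclose(
            self.ds * self.t_kelvin / 1000.0, self.dh - self.dg, rel_tol=1e-9, abs_tol=1e-9
        ), "thermodynamic identity violated"


def activation_enthalpy(ea_kj_mol: float, t_kelvin: float) -> float:
    """dH = Ea - R*T (kJ/mol)."""
    if t_kelvin <= 0:
        raise ValidationError("absolute temperature must be positive")
    return ea_kj_mol - R * t_kelvin / 1000.0


def gibbs_free_energy(k_per_min: float, t_kelvin: float) -> float:
    """dG = R*T*ln(kB*T/(h*k_s)) (kJ/mol) with k converted min^-1 -> s^-1."""
    if t_kelvin <= 0:
        raise ValidationError("absolute temperature must be positive")
    if k_per_min <= 0:
        raise ValidationError("rate constant must be positive")
    k_s = k_per_min / SECONDS_PER_MINUTE
    return R * t_kelvin * math.log(KB * t_kelvin / (H * k_s)) / 1000.0


def activation_entropy(dh_kj_mol: float, dg_kj_mol: float, t_kelvin: float) -> float:
    """dS = (dH - dG) * 1000 / T (J/(mol*K))."""
    if t_kelvin <= 0:
        raise ValidationError("absolute temperature must be positive")
    return (dh_kj_mol - dg_kj_mol) * 1000.0 / t_kelvin


def eyring_rate(dh_kj_mol: float, ds_j_mol_k: float, t_kelvin: float) -> float:
    """Invert the formalism: k (min^-1) from (dH, dS, T).

    k_s = (kB*T/h) * exp(-(dH*1000 - T*dS) / (R*T)); returned in min^-1.
    Used as a round-trip check on thermo tables.
    """
    if t_kelvin <= 0:
        raise ValidationError("absolute temperature must be positive")
    dg_j = dh_kj_mol * 1000.0 - t_kelvin * ds_j_mol_k
    k_s = (KB * t_kelvin / H) * math.exp(-dg_j / (R * t_kelvin))
    return k_s * SECONDS_PER_MINUTE


def thermo_table(
    arrhenius: ArrheniusResult,
    fits: Sequence[FirstOrderFit],
) -> list[ThermoRow]:
    """One ThermoRow per kinetic fit, ordered by temperature.

    dH comes from the single cross-temperature Ea, dG from each temperature's
    own k, dS from both. Uncertainties: dH_se is the Ea regression SE; dG_se
    propagates the replicate SD of k via |d dG/d ln k| = R*T/1000; dS_se
    combines the two in quadrature.
    """
    rows: list[ThermoRow] = []
    for fit in sorted(fits, key=lambda f: f.temperature_c):
        if fit.k <= 0:
            raise ValidationError(
                f"thermo table requires k > 0; got {fit.k} at {fit.temperature_c}°C"
            )
        t_k = celsius_to_kelvin(fit.temperature_c)
        dh = activation_enthalpy(arrhenius.ea, t_k)
        dg = gibbs_free_energy(fit.k, t_k)
        ds = activation_entropy(dh, dg, t_k)
        dh_se = arrhenius.ea_se
        if math.isfinite(fit.k_sd) and fit.k > 0:
            dg_se = R * t_k * (fit.k_sd / fit.k) / 1000.0
        else:
            dg_se = math.nan
        ds_se = (
            math.sqrt(dh_se**2 + dg_se**2) * 1000.0 / t_k
            if math.isfinite(dg_se) and math.isfinite(dh_se)
            else math.nan
        )
        rows.append(
            ThermoRow(
                analyte=fit.analyte,
                t_kelvin=t_k,
                dh=dh,
                dg=dg,
                ds=ds,
                dh_se=dh_se,
                dg_se=dg_se,
                ds_se=ds_se,
            )
        )
    return rows
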