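"""ASA-based prediction of unfolding energetics.

Empirical structure-energetics correlations map the surface area exposed
on complete unfolding, split into apolar and polar classes, onto the
unfolding heat-capacity change and the unfolding enthalpy at a 60 degC
reference temperature:

    dCp   = (0.45 * dASA_ap - 0.26 * dASA_pol) / 1000   [kcal K^-1 mol^-1]
    dH_60 = (31.4 * dASA_pol - 8.44 * dASA_ap) / 1000   [kcal mol^-1]

with areas in angstrom^2.  The enthalpy is carried to any other
temperature by Kirchhoff's relation with constant dCp.  Comparing the
predicted full-unfolding enthalpy at Tm with the calorimetric enthalpy
gives a residual-structure diagnostic: a ratio well below one indicates
that the heat-denatured state retains ordered structure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    DCP_APOLAR_COEF,
    DCP_POLAR_COEF,
    DH60_APOLAR_COEF,
    DH60_POLAR_COEF,
    DH_REFERENCE_CELSIUS,
)

__all__ = [
    "EnergeticsPrediction",
    "predict_dcp",
    "predict_dh60",
    "dh_at_temperature",
    "predict_energetics",
    "residual_structure_index",
]


def predict_dcp(dasa_ap: float, dasa_pol: float) -> float:
    """Unfolding heat-capacity change from dASA, kcal K^-1 mol^-1."""
    return (DCP_APOLAR_COEF * dasa_ap + DCP_POLAR_COEF * dasa_pol) / 1e3


def predict_dh60(dasa_ap: float, dasa_pol: float) -> float:
    """Unfolding enthalpy at 60 degC from dASA, kcal/mol."""
    return (DH60_APOLAR_COEF * dasa_ap + DH60_POLAR_COEF * dasa_pol) / 1e3


def dh_at_temperature(dh60: float, dcp: float, t_celsius: float) -> float:
    """Kirchhoff extrapolation of the unfolding enthalpy, kcal/mol."""
    return dh60 + dcp * (t_celsius - DH_REFERENCE_CELSIUS)


@dataclass(frozen=True)
class EnergeticsPrediction:
    """Predicted unfolding energetics of complete unfolding.

    All enthalpies kcal/mol, heat capacity kcal K^-1 mol^-1, areas
    angstrom^2, temperature degC.
    """

    dasa_ap: float
    dasa_pol: float
    dcp_calc: float
    dh_calc_60: float
    tm: float
    dh_calc_at_tm: float

    def as_dict(self) -> dict:
        return {
            "dasa_ap_A2": self.dasa_ap,
            "dasa_pol_A2": self.dasa_pol,
            "dcp_calc_kcal_per_K_mol": self.dcp_calc,
            "dh_calc_60_kcal": self.dh_calc_60,
            "tm_celsius": self.tm,
            "dh_calc_at_tm_kcal": self.dh_calc_at_tm,
        }


def predict_energetics(dasa_ap: float, dasa_pol: float, tm_celsius: float) -> EnergeticsPrediction:
    """Full prediction block from dASA values and a melting temperature."""
    dcp = predict_dcp(dasa_ap, dasa_pol)
    dh60 = predict_dh60(dasa_ap, dasa_pol)
    return EnergeticsPrediction(
        dasa_ap=dasa_ap,
        dasa_pol=dasa_pol,
        dcp_calc=dcp,
        dh_calc_60=dh60,
        tm=tm_celsius,
        dh_calc_at_tm=dh_at_temperature(dh60, dcp, tm_celsius),
    )


def residual_structure_index(dh_exp: float, dh_calc: float) -> float:
    """Experimental over predicted full-unfolding enthalpy.

    Values well below 1 indicate that thermal denaturation leaves a
    substantial amount of ordered (residual) structure.
    """
    if dh_calc <= 0:
        raise ValueError("predicted enthalpy must be positive")
    if dh_exp <= 0:
        raise ValueError("experimental enthalpy must be positive")
    return dh_exp / dh_calc
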