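"""Closed-form two-state thermodynamic models.

The transition between the folded (N) and thermally denatured (D) state is
modelled as a two-state equilibrium N <=> D governed by a van't Hoff
equilibrium constant

    K(T) = exp[(dH_vH / R) * (1/Tm - 1/T)],

where Tm is the temperature of half-conversion.  The excess molar heat
capacity measured by scanning calorimetry follows from the temperature
derivative of the unfolded fraction theta = K / (1 + K):

    Cp_ex(T) = dH_cal * dH_vH * K / (R * T^2 * (1 + K)^2),

with a calorimetric enthalpy dH_cal (the peak area) that may differ from
the van't Hoff enthalpy dH_vH (the peak sharpness).  Their ratio close to
unity is the standard diagnostic of a two-state monomeric transition.

All functions here work in kelvin and cal/mol; they are pure and
vectorised over temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_CAL, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "TwoStateParams",
    "CdMeltParams",
    "LinkageParams",
    "equilibrium_constant",
    "unfolded_fraction",
    "two_state_excess_cp",
    "cd_two_state_signal",
    "ligand_shifted_tm",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state transition parameters.

    Attributes
    ----------
    tm : float
        Transition (half-conversion) temperature, K.
    dh_cal : float
        Calorimetric enthalpy (area under the excess heat-capacity
        peak), cal/mol.
    dh_vh : float
        Van't Hoff enthalpy (from the transition sharpness), cal/mol.
    """

    tm: float
    dh_cal: float
    dh_vh: float

    def __post_init__(self):
        if not (self.tm > 0 and self.dh_cal > 0 and self.dh_vh > 0):
            raise ValueError(
                "tm, dh_cal and dh_vh must all be positive "
                f"(got tm={self.tm}, dh_cal={self.dh_cal}, dh_vh={self.dh_vh})"
            )

    @classmethod
    def from_celsius_kcal(cls, tm_c: float, dh_cal_kcal: float, dh_vh_kcal: float):
        """Build from reporting units (degC, kcal/mol)."""
        return cls(celsius_to_kelvin(tm_c), dh_cal_kcal * 1e3, dh_vh_kcal * 1e3)

    @property
    def tm_celsius(self) -> float:
        return kelvin_to_celsius(self.tm)

    @property
    def ratio(self) -> float:
        """Calorimetric over van't Hoff enthalpy, the two-state diagnostic."""
        return self.dh_cal / self.dh_vh


@dataclass(frozen=True)
class CdMeltParams:
    """Apparent two-state parameters of a single-wavelength CD melt.

    The optical signal is a population-weighted average of linear native
    and denatured baselines; the apparent van't Hoff enthalpy is
    independent of any calorimetric value because optical and calorimetric
    probes need not report on the same transition.

    Baselines are linear in Celsius temperature: ``intercept + slope * t_c``.
    """

    tm_app: float            # K
    dh_vh_app: float         # cal/mol
    native_intercept: float
    native_slope: float
    denatured_intercept: float
    denatured_slope: float

    def __post_init__(self):
        if not (self.tm_app > 0 and self.dh_vh_app > 0):
            raise ValueError("tm_app and dh_vh_app must be positive")

    @property
    def tm_app_celsius(self) -> float:
        return kelvin_to_celsius(self.tm_app)


@dataclass(frozen=True)
class LinkageParams:
    """Single-site ligand-binding linkage of the melting temperature.

    tm0 : ligand-free transition temperature, K.
    dh0 : unfolding enthalpy at tm0, cal/mol.
    kd : ligand dissociation constant of the native state at tm0, mol/L.
    """

    tm0: float
    dh0: float
    kd: float

    def __post_init__(self):
        if not (self.tm0 > 0 and self.dh0 > 0 and self.kd > 0):
            raise ValueError("tm0, dh0 and kd must all be positive")


def _check_temperature(t):
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be positive (kelvin)")
    return t


def equilibrium_constant(t, params: TwoStateParams):
    """Two-state equilibrium constant K(T) = exp[(dH_vH/R)(1/Tm - 1/T)].

    K equals 1 at ``params.tm`` and increases strictly with temperature
    for an endothermic (dh_vh > 0) transition.
    """
    t = _check_temperature(t)
    return np.exp((params.dh_vh / R_CAL) * (1.0 / params.tm - 1.0 / t))


def unfolded_fraction(t, params: TwoStateParams):
    """Fraction of molecules in the denatured state, theta = K/(1+K)."""
    # exp-normalised form avoids overflow far above Tm
    t = _check_temperature(t)
    x = (params.dh_vh / R_CAL) * (1.0 / params.tm - 1.0 / t)
    return 1.0 / (1.0 + np.exp(-x))


def two_state_excess_cp(t, params: TwoStateParams):
    """Excess molar heat capacity of the two-state transition, cal/(mol K).

    Cp_ex(T) = dH_cal * dH_vH * K / (R T^2 (1+K)^2).  Equivalent to
    dH_cal * d(theta)/dT, so its integral over the full transition equals
    the calorimetric enthalpy.  The peak height at Tm is
    dH_cal*dH_vH/(4 R Tm^2).
    """
    t = _check_temperature(t)
    x = (params.dh_vh / R_CAL) * (1.0 / params.tm - 1.0 / t)
    # K/(1+K)^2 = 1/(4 cosh^2(x/2)); bounded for any |x|
    sech2 = 1.0 / np.cosh(np.clip(x, -700, 700) / 2.0) ** 2
    return params.dh_cal * params.dh_vh * sech2 / (4.0 * R_CAL * t**2)


def cd_two_state_signal(t, params: CdMeltParams):
    """Mean-residue ellipticity of a two-state melt with sloping baselines.

    signal(T) = (1-theta) * native(T) + theta * denatured(T), with theta
    from the apparent van't Hoff model (tm_app, dh_vh_app).
    """
    t = _check_temperature(t)
    theta = unfolded_fraction(
        t, TwoStateParams(params.tm_app, params.dh_vh_app, params.dh_vh_app)
    )
    t_c = kelvin_to_celsius(t)
    native = params.native_intercept + params.native_slope * t_c
    denatured = params.denatured_intercept + params.denatured_slope * t_c
    return (1.0 - theta) * native + theta * denatured


def ligand_shifted_tm(ligand_conc, params: LinkageParams):
    """Melting temperature at a free-ligand concentration, K.

    For a single saturable ligand site on the native state (temperature-
    independent Kd, referenced at tm0) the transition temperature obeys

        1/Tm0 - 1/Tm(L) = (R / dH0) * ln(1 + L / Kd),

    which is solved in closed form.  Tm(0) = tm0 exactly and Tm increases
    monotonically with ligand concentration.
    """
    conc = np.asarray(ligand_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand concentration must be non-negative")
    inv_tm = 1.0 / params.tm0 - (R_CAL / params.dh0) * np.log1p(conc / params.kd)
    if np.any(inv_tm <= 0):
        raise ValueError("linkage relation has no positive-temperature solution")
    return 1.0 / inv_tm
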