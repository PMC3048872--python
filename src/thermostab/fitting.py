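"""Nonlinear least-squares estimators for melt data.

Three scikit-learn style regressors are provided:

``TwoStateCalorimetryModel``
    fits the two-state excess heat-capacity model to an excess thermogram,
    estimating (Tm, dH_cal, dH_vH);
``CdMeltModel``
    fits a two-state optical melt with sloping linear baselines (six
    parameters);
``TitrationModel``
    fits the single-site binding-linkage relation to a series of
    (ligand concentration, Tm) pairs, estimating (Tm0, Kd) with the
    unfolding enthalpy fixed by the caller.

All estimators take temperatures in degC at the public interface (kelvin
internally) and expose fitted attributes with trailing underscores, so
they compose with sklearn pipelines and model selection.  Module-level
``fit_*`` functions are thin wrappers returning a ``FitResult``.

Uncertainties are Gauss-Newton standard errors from the Jacobian at the
optimum: cov = (J^T J)^-1 * rss / (n - p).  No bootstrap by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import R_CAL, celsius_to_kelvin, kelvin_to_celsius
from .models import (
    CdMeltParams,
    LinkageParams,
    TwoStateParams,
    cd_two_state_signal,
    ligand_shifted_tm,
    two_state_excess_cp,
)
from .thermogram import MeltCurve, Thermogram, TitrationSeries

__all__ = [
    "FitResult",
    "NoTransitionError",
    "TwoStateCalorimetryModel",
    "CdMeltModel",
    "TitrationModel",
    "initial_guess",
    "fit_two_state",
    "fit_cd_melt",
    "fit_titration",
    "vant_hoff_ratio",
]

#: Relative-reduction convergence tolerance for all least-squares fits.
FIT_TOL = 1e-10
#: Iteration budget per free parameter.
MAX_ITER = 500


class NoTransitionError(ValueError):
    """The data contain no usable interior endothermic peak."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear fit.

    ``params`` is a model parameter object (kelvin / cal/mol); ``std_errors``
    maps parameter names to Gauss-Newton standard errors in the same units.
    """

    params: Any
    std_errors: dict[str, float]
    rss: float
    converged: bool
    n_points: int

    def summary(self) -> dict:
        """Parameters and errors in reporting units (degC, kcal/mol)."""
        out: dict[str, Any] = {
            "converged": bool(self.converged),
            "rss": float(self.rss),
            "n_points": int(self.n_points),
        }
        p = self.params
        se = self.std_errors
        if isinstance(p, TwoStateParams):
            out["tm_celsius"] = kelvin_to_celsius(p.tm)
            out["dh_cal_kcal"] = p.dh_cal / 1e3
            out["dh_vh_kcal"] = p.dh_vh / 1e3
            out["dh_ratio"] = p.ratio
            out["std_errors"] = {
                "tm_celsius": se.get("tm", float("nan")),
                "dh_cal_kcal": se.get("dh_cal", float("nan")) / 1e3,
                "dh_vh_kcal": se.get("dh_vh", float("nan")) / 1e3,
            }
        elif isinstance(p, CdMeltParams):
            out["tm_app_celsius"] = kelvin_to_celsius(p.tm_app)
            out["dh_vh_app_kcal"] = p.dh_vh_app / 1e3
            out["native_baseline"] = [p.native_intercept, p.native_slope]
            out["denatured_baseline"] = [p.denatured_intercept, p.denatured_slope]
            out["std_errors"] = {
                "tm_app_celsius": se.get("tm_app", float("nan")),
                "dh_vh_app_kcal": se.get("dh_vh_app", float("nan")) / 1e3,
            }
        elif isinstance(p, LinkageParams):
            out["tm0_celsius"] = kelvin_to_celsius(p.tm0)
            out["kd_molar"] = p.kd
            out["dh0_kcal"] = p.dh0 / 1e3
            out["std_errors"] = {
                "tm0_celsius": se.get("tm0", float("nan")),
                "kd_molar": se.get("kd", float("nan")),
            }
        return out


def _as_1d(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x.ravel()
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D (or a single-column 2-D array)")
    return x


def _std_errors(res, n, names):
    """Gauss-Newton standard errors from the Jacobian at the optimum.

    Directions the data do not constrain (numerically singular Jacobian
    columns) get infinite errors rather than misleadingly small ones.
    """
    p = len(names)
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof  # cost = 0.5 * rss
    jtj = res.jac.T @ res.jac
    errors = {}
    diag = np.diag(jtj)
    scale = np.max(diag) if np.max(diag) > 0 else 1.0
    cov = np.linalg.pinv(jtj) * s2
    for i, name in enumerate(names):
        if diag[i] <= 1e-12 * scale:
            errors[name] = float("inf")
        else:
            errors[name] = float(np.sqrt(max(cov[i, i], 0.0)))
    return errors


# ---------------------------------------------------------------------------
# DSC


def initial_guess(excess: Thermogram) -> TwoStateParams:
    """Moment-based starting values for the two-state heat-capacity fit.

    Tm from the interior peak position (lowest index on plateaus), the
    calorimetric enthalpy from the trapezoidal area, and the van't Hoff
    enthalpy by inverting the peak-height identity
    Cp_max = dH_cal * dH_vH / (4 R Tm^2).
    """
    t = excess.temperature_k
    y = excess.values
    i = int(np.argmax(y))  # argmax takes the first (lowest-T) maximiser
    if y[i] <= 0:
        raise NoTransitionError("no positive peak in the excess curve")
    if i == 0 or i == y.size - 1:
        raise NoTransitionError("peak lies on the grid edge; transition not resolved")
    tm = float(t[i])
    dh_cal = float(np.trapezoid(np.clip(y, 0.0, None), t))
    if dh_cal <= 0:
        raise NoTransitionError("non-positive peak area")
    dh_vh = 4.0 * R_CAL * tm**2 * float(y[i]) / dh_cal
    return TwoStateParams(tm=tm, dh_cal=dh_cal, dh_vh=dh_vh)


class TwoStateCalorimetryModel(RegressorMixin, BaseEstimator):
    """Two-state excess heat-capacity regressor.

    Fits Cp_ex(T) = dH_cal * dH_vH * K / (R T^2 (1+K)^2) to an excess
    thermogram by bounded least squares (all three parameters positive).

    Parameters
    ----------
    tol : float
        Relative-reduction convergence tolerance.
    max_iter : int
        Iteration budget per free parameter.

    Attributes
    ----------
    tm_celsius_ : float
        Fitted transition temperature, degC.
    dh_cal_kcal_, dh_vh_kcal_ : float
        Fitted calorimetric and van't Hoff enthalpies, kcal/mol.
    params_ : TwoStateParams
        Fitted parameters in kelvin / cal/mol.
    result_ : FitResult
    """

    def __init__(self, tol: float = FIT_TOL, max_iter: int = MAX_ITER):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Fit to temperatures ``X`` (degC) and excess Cp ``y`` (cal/(mol K))."""
        t_c = _as_1d(X, "X")
        cp = _as_1d(y, "y")
        if t_c.shape != cp.shape:
            raise ValueError("X and y must have equal length")
        t_k = celsius_to_kelvin(t_c)
        order = np.argsort(t_k)
        guess_tg = Thermogram(t_k[order], cp[order], stage="excess")
        p0 = initial_guess(guess_tg)

        def resid(x):
            return two_state_excess_cp(t_k, TwoStateParams(*x)) - cp

        res = least_squares(
            resid,
            x0=[p0.tm, p0.dh_cal, p0.dh_vh],
            bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=self.tol,
            ftol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_iter * 3,
            x_scale=[p0.tm, p0.dh_cal, p0.dh_vh],
        )
        self.params_ = TwoStateParams(*res.x)
        self.tm_celsius_ = kelvin_to_celsius(self.params_.tm)
        self.dh_cal_kcal_ = self.params_.dh_cal / 1e3
        self.dh_vh_kcal_ = self.params_.dh_vh / 1e3
        self.n_points_ = t_c.size
        self.result_ = FitResult(
            params=self.params_,
            std_errors=_std_errors(res, t_c.size, ["tm", "dh_cal", "dh_vh"]),
            rss=float(2.0 * res.cost),
            converged=bool(res.success),
            n_points=t_c.size,
        )
        return self

    def predict(self, X):
        """Model Cp_ex (cal/(mol K)) at temperatures ``X`` in degC."""
        t_k = celsius_to_kelvin(_as_1d(X, "X"))
        return two_state_excess_cp(t_k, self.params_)


def fit_two_state(excess: Thermogram) -> FitResult:
    """Fit the two-state model to an excess-stage thermogram."""
    if excess.stage != "excess":
        raise ValueError("fit_two_state expects an excess-stage thermogram")
    est = TwoStateCalorimetryModel()
    est.fit(excess.temperature_c, excess.values)
    return est.result_


def vant_hoff_ratio(params: TwoStateParams) -> float:
    """dH_cal / dH_vH; values near 1 support a two-state monomer transition."""
    return params.ratio


# ---------------------------------------------------------------------------
# CD melts


class CdMeltModel(RegressorMixin, BaseEstimator):
    """Two-state optical melt regressor with sloping linear baselines.

    Six free parameters: apparent midpoint and van't Hoff enthalpy plus
    intercept and slope of the native and denatured baselines (baselines
    linear in degC).

    Attributes (after ``fit``): ``tm_app_celsius_``, ``dh_vh_app_kcal_``,
    ``params_`` (CdMeltParams), ``result_`` (FitResult).
    """

    def __init__(self, tol: float = FIT_TOL, max_iter: int = MAX_ITER,
                 baseline_fraction: float = 0.15):
        self.tol = tol
        self.max_iter = max_iter
        self.baseline_fraction = baseline_fraction

    def _guess(self, t_c, sig):
        n = t_c.size
        k = max(int(round(self.baseline_fraction * n)), 2)
        nat = np.polynomial.polynomial.polyfit(t_c[:k], sig[:k], 1)
        den = np.polynomial.polynomial.polyfit(t_c[-k:], sig[-k:], 1)
        # midpoint: temperature where the baseline-corrected signal crosses 1/2
        nat_line = nat[0] + nat[1] * t_c
        den_line = den[0] + den[1] * t_c
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = (sig - nat_line) / (den_line - nat_line)
        frac = np.clip(np.nan_to_num(frac, nan=0.5), 0.0, 1.0)
        i = int(np.argmin(np.abs(frac - 0.5)))
        tm_c = float(t_c[i])
        return nat, den, tm_c

    def fit(self, X, y):
        """Fit to temperatures ``X`` (degC) and melt signal ``y``."""
        t_c = _as_1d(X, "X")
        sig = _as_1d(y, "y")
        if t_c.shape != sig.shape:
            raise ValueError("X and y must have equal length")
        if t_c.size < 20:
            raise ValueError("need >= 20 points spanning the transition")
        t_k = celsius_to_kelvin(t_c)
        nat, den, tm_c_guess = self._guess(t_c, sig)
        x0 = [celsius_to_kelvin(tm_c_guess), 1.0e5, nat[0], nat[1], den[0], den[1]]
        lo = [t_k.min(), 1e3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [t_k.max(), 1e8, np.inf, np.inf, np.inf, np.inf]
        scale = [300.0, 1e5, max(abs(nat[0]), 1.0), max(abs(nat[1]), 0.1),
                 max(abs(den[0]), 1.0), max(abs(den[1]), 0.1)]

        def resid(x):
            return cd_two_state_signal(t_k, CdMeltParams(*x)) - sig

        res = least_squares(
            resid, x0=x0, bounds=(lo, hi),
            xtol=self.tol, ftol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter * 6, x_scale=scale,
        )
        self.params_ = CdMeltParams(*res.x)
        self.tm_app_celsius_ = kelvin_to_celsius(self.params_.tm_app)
        self.dh_vh_app_kcal_ = self.params_.dh_vh_app / 1e3
        self.n_points_ = t_c.size
        names = ["tm_app", "dh_vh_app", "native_intercept", "native_slope",
                 "denatured_intercept", "denatured_slope"]
        self.result_ = FitResult(
            params=self.params_,
            std_errors=_std_errors(res, t_c.size, names),
            rss=float(2.0 * res.cost),
            converged=bool(res.success),
            n_points=t_c.size,
        )
        return self

    def predict(self, X):
        t_k = celsius_to_kelvin(_as_1d(X, "X"))
        return cd_two_state_signal(t_k, self.params_)


def fit_cd_melt(melt: MeltCurve) -> FitResult:
    """Fit the two-state melt model to a CD melt curve."""
    est = CdMeltModel()
    est.fit(melt.temperature_c, melt.signal)
    return est.result_


# ---------------------------------------------------------------------------
# Tm titrations


class TitrationModel(RegressorMixin, BaseEstimator):
    """Single-site binding-linkage regressor for Tm vs ligand concentration.

    Estimates the ligand-free midpoint Tm0 and the native-state
    dissociation constant Kd; the unfolding enthalpy at Tm0 is fixed to a
    calorimetric value supplied by the caller (``dh0_cal``, cal/mol),
    because a sparse titration cannot constrain it independently.
    """

    def __init__(self, dh0_cal: float, tol: float = FIT_TOL, max_iter: int = MAX_ITER):
        self.dh0_cal = dh0_cal
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Fit to ligand concentrations ``X`` (mol/L) and midpoints ``y`` (degC)."""
        conc = _as_1d(X, "X")
        tm_c = _as_1d(y, "y")
        if conc.shape != tm_c.shape:
            raise ValueError("X and y must have equal length")
        if conc.size < 4:
            raise ValueError("need >= 4 (concentration, Tm) pairs")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.any(conc == 0):
            warnings.warn(
                "no zero-concentration anchor in the titration; Tm0 is "
                "extrapolated",
                UserWarning,
                stacklevel=2,
            )
        tm_k = celsius_to_kelvin(tm_c)
        tm0_guess = float(tm_k[np.argmin(conc)])
        pos = conc[conc > 0]
        kd_guess = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1e-6

        def resid(x):
            tm0, kd = x
            return ligand_shifted_tm(conc, LinkageParams(tm0, self.dh0_cal, kd)) - tm_k

        res = least_squares(
            resid,
            x0=[tm0_guess, kd_guess],
            bounds=([1e-6, 1e-300], [np.inf, np.inf]),
            xtol=self.tol, ftol=self.tol, gtol=self.tol,
            max_nfev=self.max_iter * 2,
            x_scale=[tm0_guess, kd_guess],
        )
        self.params_ = LinkageParams(res.x[0], self.dh0_cal, res.x[1])
        self.tm0_celsius_ = kelvin_to_celsius(self.params_.tm0)
        self.kd_molar_ = self.params_.kd
        self.n_points_ = conc.size
        self.result_ = FitResult(
            params=self.params_,
            std_errors=_std_errors(res, conc.size, ["tm0", "kd"]),
            rss=float(2.0 * res.cost),
            converged=bool(res.success),
            n_points=conc.size,
        )
        return self

    def predict(self, X):
        """Predicted midpoints (degC) at ligand concentrations ``X`` (mol/L)."""
        conc = _as_1d(X, "X")
        return kelvin_to_celsius(ligand_shifted_tm(conc, self.params_))


def fit_titration(series: TitrationSeries, dh0_cal: float) -> FitResult:
    """Fit the linkage model to a titration series; dh0_cal in cal/mol."""
    est = TitrationModel(dh0_cal=dh0_cal)
    est.fit(series.conc_molar, kelvin_to_celsius(series.tm_k))
    return est.result_
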