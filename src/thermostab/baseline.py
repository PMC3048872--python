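"""Raw scan to excess heat capacity: reference subtraction, molar
normalisation, and chemical (progress) baseline removal.

The chemical baseline is the smooth heat-capacity trend that would be
observed if no transition occurred: the native-state trend below the peak,
the denatured-state trend above it, and a connection across the transition
region.  Following standard scanning-calorimetry practice the connection is
weighted by the extent of conversion, estimated iteratively from the
running integral of the excess signal itself, starting from a cubic
(value- and slope-matched) connector between the two linear trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .thermogram import (
    IncompatibleGridsError,
    MissingMetadataError,
    Thermogram,
)

__all__ = [
    "BaselineSpec",
    "subtract_reference",
    "to_molar",
    "remove_chemical_baseline",
    "default_windows",
]


class InvalidWindowError(ValueError):
    """A baseline window is empty or mis-ordered."""


@dataclass(frozen=True)
class BaselineSpec:
    """Pre/post-transition windows (kelvin intervals) and connector degree."""

    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    polynomial_degree: int = 3

    def __post_init__(self):
        pre_lo, pre_hi = self.pre_window
        post_lo, post_hi = self.post_window
        if not (pre_lo < pre_hi and post_lo < post_hi):
            raise InvalidWindowError("windows must be (low, high) with low < high")
        if pre_hi >= post_lo:
            raise InvalidWindowError("pre window must lie entirely below post window")
        if self.polynomial_degree < 1:
            raise InvalidWindowError("polynomial degree must be >= 1")


def default_windows(tg: Thermogram, fraction: float = 0.15) -> BaselineSpec:
    """Windows spanning the lowest and highest ``fraction`` of the grid."""
    t = tg.temperature_k
    span = t[-1] - t[0]
    return BaselineSpec(
        pre_window=(t[0], t[0] + fraction * span),
        post_window=(t[-1] - fraction * span, t[-1]),
    )


def subtract_reference(sample: Thermogram, reference: Thermogram) -> Thermogram:
    """Subtract a buffer-buffer reference scan from a sample scan.

    The reference is interpolated linearly onto the sample grid; sample
    points outside the reference range are dropped (no extrapolation).
    """
    if sample.stage != "raw" or reference.stage != "raw":
        raise ValueError("reference subtraction operates on raw-stage scans")
    lo = max(sample.temperature_k[0], reference.temperature_k[0])
    hi = min(sample.temperature_k[-1], reference.temperature_k[-1])
    if lo >= hi:
        raise IncompatibleGridsError(
            "sample and reference temperature ranges do not overlap"
        )
    keep = (sample.temperature_k >= lo) & (sample.temperature_k <= hi)
    t = sample.temperature_k[keep]
    ref = np.interp(t, reference.temperature_k, reference.values)
    return Thermogram(
        temperature_k=t,
        values=sample.values[keep] - ref,
        scan_rate_k_per_min=sample.scan_rate_k_per_min,
        protein_conc_molar=sample.protein_conc_molar,
        cell_volume_l=sample.cell_volume_l,
        stage="reference_subtracted",
        meta=dict(sample.meta),
    )


def to_molar(tg: Thermogram) -> Thermogram:
    """Normalise per-cell heat capacity to molar units.

    Divides by the moles of protein in the calorimeter cell
    (concentration x cell volume).
    """
    if tg.protein_conc_molar is None or tg.cell_volume_l is None:
        raise MissingMetadataError(
            "molar normalisation needs protein_conc_molar and cell_volume_l"
        )
    if tg.protein_conc_molar <= 0 or tg.cell_volume_l <= 0:
        raise MissingMetadataError("concentration and cell volume must be positive")
    moles = tg.protein_conc_molar * tg.cell_volume_l
    return tg.with_values(tg.values / moles, stage="molar")


def _linear_trend(t, y, window, name):
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 5:
        raise InvalidWindowError(
            f"{name} window [{lo:.2f}, {hi:.2f}] K contains "
            f"{int(mask.sum())} points; need >= 5"
        )
    coeffs = np.polynomial.polynomial.polyfit(t[mask], y[mask], 1)
    return coeffs  # (intercept, slope)


def remove_chemical_baseline(
    tg: Thermogram,
    spec: BaselineSpec | None = None,
    max_iter: int = 20,
    tol: float = 1e-6,
):
    """Remove the chemical baseline, returning (excess, baseline).

    Linear trends are fitted in the pre- and post-transition windows and
    joined across the transition, first by a cubic matching value and
    slope at the inner window edges, then refined by progress weighting:
    baseline(T) = (1-alpha) * pre(T) + alpha * post(T) with alpha the
    normalised running integral of the current excess signal.  Iteration
    stops when the baseline changes by less than ``tol`` (relative to the
    peak scale) or after ``max_iter`` passes, whichever is first.

    Returns
    -------
    excess : Thermogram
        Stage ``excess``; values are molar heat capacity minus baseline.
    baseline : ndarray
        The removed baseline, same grid as the input.
    """
    if tg.stage != "molar":
        raise ValueError("chemical baseline removal expects a molar-stage thermogram")
    if spec is None:
        spec = default_windows(tg)
    t = tg.temperature_k
    y = tg.values

    pre = _linear_trend(t, y, spec.pre_window, "pre")
    post = _linear_trend(t, y, spec.post_window, "post")
    pre_line = pre[0] + pre[1] * t
    post_line = post[0] + post[1] * t

    t1 = spec.pre_window[1]
    t2 = spec.post_window[0]
    mid = (t > t1) & (t < t2)

    # initial connector: cubic matched to value and slope of each trend
    hermite = CubicHermiteSpline(
        [t1, t2],
        [pre[0] + pre[1] * t1, post[0] + post[1] * t2],
        [pre[1], post[1]],
    )
    baseline = np.where(t <= t1, pre_line, np.where(t >= t2, post_line, 0.0))
    baseline[mid] = hermite(t[mid])

    # convergence scale: the transition signal, floored at rounding noise
    # of the input so a transition-free (pure trend) scan converges at once
    scale = max(
        np.max(np.abs(y - baseline)),
        1e-9 * max(1.0, float(np.max(np.abs(y)))),
    )
    converged = False
    for _ in range(max_iter):
        excess = np.clip(y - baseline, 0.0, None)
        area = np.concatenate(
            ([0.0], np.cumsum(np.diff(t) * 0.5 * (excess[1:] + excess[:-1])))
        )
        total = area[-1]
        alpha = area / total if total > 0 else np.zeros_like(area)
        new_baseline = np.where(t <= t1, pre_line, np.where(t >= t2, post_line, 0.0))
        new_baseline[mid] = (1.0 - alpha[mid]) * pre_line[mid] + alpha[mid] * post_line[mid]
        delta = np.max(np.abs(new_baseline - baseline)) / scale
        baseline = new_baseline
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "progress-baseline iteration did not converge; using last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    excess_tg = tg.with_values(y - baseline, stage="excess")
    return excess_tg, baseline
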