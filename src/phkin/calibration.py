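"""Optical calibrations: absorbance -> amount and pHluorin ratio -> pH.

Plate-reader absorbance is converted to the amount of the monitored
species through a linear calibration line Abs = a * amount + b measured
once per optical species; the packaged defaults are the published lines
for NAD(P)H at 340 nm and PEP at 240 nm.  The line absorbs the molar
absorption coefficient and the optical path length, so no separate
path-length input exists.

Cytosolic pH is read out from the pHluorin excitation ratio R390/470
through a degree-3 polynomial fitted to an in vivo titration
(permeabilized cells in buffers of known pH).  The polynomial maps
ratio -> pH directly, which is the direction needed at run time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LinearCalibration:
    """Linear absorbance calibration: amount (umol) = (Abs - b) / a."""

    species: str
    slope: float  # a, absorbance units per umol
    intercept: float  # b, absorbance units

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


#: published calibration lines (absorbance per umol in the assay well)
NADH_CALIBRATION = LinearCalibration("NAD(P)H", 4.8365, 0.0628)
PEP_CALIBRATION = LinearCalibration("PEP", 1.223, -0.008)


def calibration_for(species: str) -> LinearCalibration:
    """Packaged calibration line for a monitored species name."""
    if species.upper() in ("NADH", "NADPH", "NAD(P)H"):
        return NADH_CALIBRATION
    if species.upper() == "PEP":
        return PEP_CALIBRATION
    raise KeyError(f"no packaged calibration for species {species!r}")


def abs_to_conc(absorbance, cal: LinearCalibration):
    """Amount (umol in the well) from absorbance.

    May be slightly negative for blank noise; not clamped.
    """
    return (np.asarray(absorbance, dtype=float) - cal.intercept) / cal.slope


def conc_to_abs(amount_umol, cal: LinearCalibration):
    """Exact inverse of :func:`abs_to_conc`."""
    return np.asarray(amount_umol, dtype=float) * cal.slope + cal.intercept


class ExtrapolationError(ValueError):
    """A ratio falls outside the calibrated range."""


@dataclass
class PHluorinCalibration:
    """Degree-3 polynomial mapping R390/470 -> pH.

    ``coefficients`` are in ascending order (c0 + c1*r + c2*r^2 + c3*r^3).
    Queries outside ``valid_ratio_range`` (with a configurable relative
    slack) raise :class:`ExtrapolationError` rather than extrapolating
    silently.
    """

    coefficients: np.ndarray
    valid_ratio_range: tuple[float, float]
    valid_ph_range: tuple[float, float]
    slack: float = 0.05

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ValueError("expected 4 polynomial coefficients")

    def is_monotone(self, n_grid: int = 1000) -> bool:
        lo, hi = self.valid_ratio_range
        grid = np.linspace(lo, hi, n_grid)
        values = np.polynomial.polynomial.polyval(grid, self.coefficients)
        d = np.diff(values)
        return bool(np.all(d >= 0) or np.all(d <= 0))

    def __call__(self, ratio):
        return ratio_to_ph(ratio, self)


def fit_phluorin_poly(titration, degree: int = 3) -> PHluorinCalibration:
    """Least-squares degree-3 fit of pH as a function of R390/470.

    ``titration`` is an iterable of (ratio, pH) pairs (or a 2-column
    array); at least five points are required.  A non-monotone fitted
    polynomial over the observed ratio range raises a warning.
    """
    arr = np.asarray(list(map(tuple, titration)), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("titration must be (ratio, pH) pairs")
    if arr.shape[0] < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} titration points, got {arr.shape[0]}"
        )
    ratio, ph = arr[:, 0], arr[:, 1]
    if np.ptp(ratio) == 0:
        raise ValueError("titration ratios are rank deficient (all equal)")
    coeffs = np.polynomial.polynomial.polyfit(ratio, ph, degree)
    cal = PHluorinCalibration(
        coefficients=coeffs,
        valid_ratio_range=(float(ratio.min()), float(ratio.max())),
        valid_ph_range=(float(ph.min()), float(ph.max())),
    )
    if not cal.is_monotone():
        warnings.warn(
            "fitted pHluorin polynomial is not monotone over the titration "
            "ratio range; calibration may be unreliable",
            stacklevel=2,
        )
    return cal


def ratio_to_ph(ratio, cal: PHluorinCalibration):
    """Evaluate the calibration polynomial at ``ratio`` (scalar or array)."""
    r = np.asarray(ratio, dtype=float)
    lo, hi = cal.valid_ratio_range
    span = hi - lo
    if np.any(r < lo - cal.slack * span) or np.any(r > hi + cal.slack * span):
        raise ExtrapolationError(
            f"ratio outside calibrated range [{lo:.4g}, {hi:.4g}] "
            f"(slack {cal.slack:.0%})"
        )
    out = np.polynomial.polynomial.polyval(r, cal.coefficients)
    return float(out) if np.isscalar(ratio) else out
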