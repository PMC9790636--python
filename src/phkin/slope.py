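"""Slope-based ("direct") Vmax estimation from progression curves.

The classical estimator: find the maximal initial window of the
progression curve over which the absorbance trace is still linear
(anchored at the first post-start sample and extended for as long as the
regression R^2 stays above 0.995), take the regression slope, subtract
the background rate measured before substrate addition, convert through
the absorbance calibration line, and normalize by dilution factors and
extract protein to an enzyme capacity in umol/min per mg protein.

Estimates from a dilution series of the cell-free extract must agree
after dilution correction; dilution factors falling outside the linear
regime are discarded (largest subset within 25% of its median), and the
retained curves are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import linregress

from .calibration import LinearCalibration, calibration_for


class EstimationError(RuntimeError):
    """A progression curve or dilution series cannot be estimated."""


@dataclass
class ProgressionCurve:
    """One well's absorbance trace with its metadata and background trace.

    Times are minutes from reaction start; the optional background trace
    (times, absorbance) covers the pre-start window (about 5 min of the
    enzyme mix without the start chemical).
    """

    enzyme_id: str
    ph: float
    dilution_factor: float
    replicate: int
    times: np.ndarray  # min
    absorbance: np.ndarray  # AU
    background: tuple[np.ndarray, np.ndarray] | None = None
    wavelength: float = 340.0
    direction: str = "decrease"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.background is not None:
            bt, ba = self.background
            self.background = (np.asarray(bt, dtype=float), np.asarray(ba, dtype=float))


@dataclass
class VmaxEstimate:
    """Aggregated per-(enzyme, pH) capacity estimate."""

    enzyme_id: str
    ph: float
    method: str  # "slope" | "fit"
    value: float  # umol/min/mg protein
    spread: float = 0.0  # half-range across retained curves
    r_squared: float = float("nan")  # worst window R^2 among retained curves
    window: tuple[int, int] | None = None
    dilution_factors_used: list[float] = field(default_factory=list)
    flagged: bool = False  # negative after background correction


def background_rate(curve: ProgressionCurve) -> float:
    """OLS slope (AU/min) of the pre-start background trace.

    Returns 0 with a warning when no background trace is present; fewer
    than three background points is an error.
    """
    if curve.background is None:
        warnings.warn(
            f"{curve.enzyme_id} pH {curve.ph}: no background trace; "
            "assuming zero background rate",
            stacklevel=2,
        )
        return 0.0
    bt, ba = curve.background
    if len(bt) < 3:
        raise EstimationError("background trace has fewer than 3 points")
    return float(linregress(bt, ba).slope)


def _ols_with_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and coefficient of determination.

    A perfectly flat trace is a perfect linear fit (R^2 = 1, slope 0);
    ``scipy.stats.linregress`` would report an undefined correlation there.
    """
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-20:
        return float(slope), 1.0 if ss_res < 1e-20 else 0.0
    return float(slope), 1.0 - ss_res / ss_tot


def find_linear_window(
    curve: ProgressionCurve,
    r2_threshold: float = 0.995,
    min_points: int = 5,
    lag_skip: int = 0,
) -> tuple[tuple[int, int], float, float]:
    """Maximal initial linear window of the reaction trace.

    The window is anchored at the first post-start sample (optionally
    skipping ``lag_skip`` points for mixing lags) and extended to the
    largest end index whose regression keeps R^2 >= ``r2_threshold``.
    Returns ((start, end) inclusive indices, slope AU/min, R^2).
    """
    t = curve.times[lag_skip:]
    y = curve.absorbance[lag_skip:]
    if len(t) < min_points:
        raise EstimationError(
            f"{curve.enzyme_id} pH {curve.ph}: fewer than {min_points} "
            "points after reaction start"
        )
    best = None
    for end in range(min_points - 1, len(t)):
        slope, r2 = _ols_with_r2(t[: end + 1], y[: end + 1])
        if r2 >= r2_threshold:
            best = ((lag_skip, lag_skip + end), slope, r2)
    if best is None:
        raise EstimationError(
            f"{curve.enzyme_id} pH {curve.ph} DF {curve.dilution_factor} "
            f"rep {curve.replicate}: no window of >= {min_points} points "
            f"reaches R^2 >= {r2_threshold}"
        )
    return best


def slope_to_capacity(
    slope: float,
    cal: LinearCalibration,
    protein: float,
    df_sample: float,
    df_assay: float = 60.0,
    stoich: int = 1,
    assay_volume_ml: float = 0.3,
) -> float:
    """Convert a background-corrected optical slope to enzyme capacity.

    ``slope`` is AU/min; ``protein`` is the cell-free extract protein
    concentration (mg/mL); ``df_sample`` the extract dilution factor and
    ``df_assay`` the extract-to-assay dilution (60x).  ``stoich`` divides
    out multiple monitored turnovers per test-reaction turnover.

    capacity = (|slope| / a) * df_sample * df_assay
               / (protein * assay_volume * stoich)    [umol/min/mg]
    """
    if protein <= 0:
        raise ValueError(f"protein concentration must be > 0, got {protein}")
    amount_rate = abs(slope) / cal.slope  # umol/min in the well
    return amount_rate * df_sample * df_assay / (protein * assay_volume_ml * stoich)


def select_dilution_factors(
    estimates: dict[float, float],
    tolerance: float = 0.25,
    enzyme_id: str = "",
) -> list[float]:
    """Retain the largest dilution-factor subset in the linear regime.

    A subset is consistent when every member's dilution-corrected capacity
    deviates at most ``tolerance`` from the subset median.  At least two
    consistent dilutions are required; ties prefer the tighter subset.
    """
    if len(estimates) < 2:
        raise EstimationError(
            f"{enzyme_id}: need >= 2 dilution factors, got {len(estimates)}"
        )
    best: list[float] | None = None
    best_spread = np.inf
    dfs = sorted(estimates)
    for size in range(len(dfs), 1, -1):
        for subset in combinations(dfs, size):
            values = np.array([estimates[d] for d in subset])
            med = np.median(values)
            if np.max(np.abs(values)) < 1e-9:  # all capacities are zero
                consistent = True
            elif med == 0:
                consistent = np.all(values == 0)
            else:
                consistent = np.all(np.abs(values - med) <= tolerance * abs(med))
            if consistent:
                spread = float(np.ptp(values))
                if best is None or len(subset) > len(best) or (
                    len(subset) == len(best) and spread < best_spread
                ):
                    best = list(subset)
                    best_spread = spread
        if best is not None:
            break
    if best is None:
        raise EstimationError(
            f"{enzyme_id}: no two dilution factors agree within "
            f"{tolerance:.0%}; estimates {estimates}"
        )
    return best


def estimate_vmax_slope(
    curves: Iterable[ProgressionCurve],
    cal: LinearCalibration | None = None,
    protein: float = 6.0,
    df_assay: float = 60.0,
    stoich: int = 1,
    assay_volume_ml: float = 0.3,
    r2_threshold: float = 0.995,
    df_tolerance: float = 0.25,
    lag_skip: int = 0,
    monitored_species: str | None = None,
) -> list[VmaxEstimate]:
    """Full slope pipeline, one estimate per (enzyme, pH).

    background_rate -> find_linear_window -> slope_to_capacity ->
    select_dilution_factors -> mean over retained curves.  Curves whose
    linear window cannot be found are dropped with a warning; estimates
    whose corrected slope opposes the assay direction are flagged.
    """
    curves = list(curves)
    if cal is None:
        if monitored_species is None:
            monitored_species = "NADH" if curves[0].wavelength == 340 else "PEP"
        cal = calibration_for(monitored_species)
    groups: dict[tuple[str, float], list[ProgressionCurve]] = {}
    for c in curves:
        groups.setdefault((c.enzyme_id, c.ph), []).append(c)

    estimates = []
    for (enzyme_id, ph), group in sorted(groups.items()):
        per_curve: dict[float, list[tuple[float, float]]] = {}  # df -> [(cap, r2)]
        sign = 1.0 if group[0].direction == "increase" else -1.0
        for c in group:
            try:
                (_, _), slope, r2 = find_linear_window(
                    c, r2_threshold=r2_threshold, lag_skip=lag_skip
                )
            except EstimationError as exc:
                warnings.warn(f"dropping curve: {exc}", stacklevel=2)
                continue
            corrected = (slope - background_rate(c)) * sign
            cap = slope_to_capacity(
                corrected, cal, protein, c.dilution_factor, df_assay,
                stoich, assay_volume_ml,
            )
            if corrected < 0:
                cap = -cap
            per_curve.setdefault(c.dilution_factor, []).append((cap, r2))
        if not per_curve:
            raise EstimationError(f"{enzyme_id} pH {ph}: no usable curves")
        per_df = {df: float(np.mean([v for v, _ in vals]))
                  for df, vals in per_curve.items()}
        retained = select_dilution_factors(per_df, df_tolerance, enzyme_id)
        values = [v for df in retained for v, _ in per_curve[df]]
        r2s = [r for df in retained for _, r in per_curve[df]]
        value = float(np.mean(values))
        estimates.append(VmaxEstimate(
            enzyme_id=enzyme_id,
            ph=ph,
            method="slope",
            value=value,
            spread=float(np.ptp(values)) / 2.0,
            r_squared=float(np.min(r2s)),
            dilution_factors_used=sorted(retained),
            flagged=value < 0,
        ))
    return estimates
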