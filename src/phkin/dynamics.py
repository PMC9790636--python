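"""Projecting activity-vs-pH profiles onto intracellular pH dynamics.

During glucose feast/famine cycling the yeast cytosol acidifies from
about pH 7.1 to 6.4 within minutes.  Given an enzyme's measured capacity
at each assayed pH, interpolating that profile along a cytosolic pH time
trace yields the expected relative enzyme activity over the cycle, and a
per-enzyme percent change between the feast and famine pH levels.

Interpolation is piecewise linear between assayed points (no overshoot
between knots); a monotone cubic option exists for smoother plots but
linear is the default used everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator


@dataclass
class PHTrace:
    """A cytosolic pH time trace (times in minutes)."""

    times: np.ndarray
    ph: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.times.shape != self.ph.shape:
            raise ValueError("times and ph must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.ph < 4.0) | (self.ph > 9.0)):
            raise ValueError("pH outside the physiological sanity band [4, 9]")


@dataclass
class ActivityProfile:
    """An enzyme's capacity as a function of assayed pH.

    ``clamp_band`` (pH units) tolerates queries slightly outside the
    assayed range by clamping, with a warning; beyond it queries fail.
    """

    enzyme_id: str
    ph: np.ndarray
    vmax: np.ndarray
    clamp_band: float = 0.05
    method: str = "linear"  # "linear" | "pchip"

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.vmax = np.asarray(self.vmax, dtype=float)
        if len(self.ph) < 2:
            raise ValueError(f"{self.enzyme_id}: need >= 2 (pH, Vmax) points")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError(f"{self.enzyme_id}: pH values must be strictly increasing")
        if np.any(self.vmax < 0):
            raise ValueError(f"{self.enzyme_id}: negative Vmax")
        if self.method not in ("linear", "pchip"):
            raise ValueError(f"unknown interpolation method {self.method!r}")

    def __call__(self, ph):
        return activity_at_ph(self, ph)


def activity_at_ph(profile: ActivityProfile, ph):
    """Interpolated capacity at ``ph`` (scalar or array).

    Exact at assayed points.  Queries within ``clamp_band`` outside the
    assayed range are clamped with a warning; farther out is an error.
    """
    p = np.atleast_1d(np.asarray(ph, dtype=float))
    lo, hi = profile.ph[0], profile.ph[-1]
    band = profile.clamp_band
    if np.any(p < lo - band) or np.any(p > hi + band):
        raise ValueError(
            f"{profile.enzyme_id}: pH query outside assayed range "
            f"[{lo}, {hi}] by more than {band} units"
        )
    if np.any(p < lo) or np.any(p > hi):
        warnings.warn(
            f"{profile.enzyme_id}: pH query clamped to assayed range "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
        p = np.clip(p, lo, hi)
    if profile.method == "pchip":
        out = PchipInterpolator(profile.ph, profile.vmax)(p)
    else:
        out = np.interp(p, profile.ph, profile.vmax)
    return float(out[0]) if np.isscalar(ph) else out


def activity_trace(profile: ActivityProfile, trace: PHTrace) -> np.ndarray:
    """Relative-activity time series along a pH trace.

    Pointwise interpolation of the profile, normalized to the activity at
    the trace's maximum pH (the feast level), so values are 1 at the most
    permissive pH seen in the trace.
    """
    activities = activity_at_ph(profile, trace.ph)
    ref = activity_at_ph(profile, float(np.max(trace.ph)))
    if ref == 0:
        raise ValueError(f"{profile.enzyme_id}: zero activity at reference pH")
    return activities / ref


def transition_summary(
    profiles: dict[str, ActivityProfile],
    ph_hi: float = 7.1,
    ph_lo: float = 6.4,
    threshold_pct: float = 60.0,
) -> pd.DataFrame:
    """Per-enzyme percent activity change between two pH levels.

    percent_change = 100 * (V(ph_hi) - V(ph_lo)) / V(ph_hi); positive
    values are activity losses upon acidification.  ``flagged`` marks
    decreases above ``threshold_pct``.
    """
    rows = []
    for enzyme_id, profile in profiles.items():
        v_hi = activity_at_ph(profile, ph_hi)
        v_lo = activity_at_ph(profile, ph_lo)
        change = 100.0 * (v_hi - v_lo) / v_hi
        rows.append({
            "enzyme": enzyme_id,
            "v_hi": v_hi,
            "v_lo": v_lo,
            "percent_change": change,
            "flagged": change > threshold_pct,
        })
    return pd.DataFrame(rows).set_index("enzyme")


def profiles_from_frame(df: pd.DataFrame, **kwargs) -> dict[str, ActivityProfile]:
    """Build profiles from a tidy frame with columns enzyme, ph, vmax."""
    out = {}
    for enzyme, grp in df.groupby("enzyme"):
        grp = grp.sort_values("ph")
        out[str(enzyme)] = ActivityProfile(
            str(enzyme), grp["ph"].to_numpy(), grp["vmax"].to_numpy(), **kwargs
        )
    return out


def load_packaged_profiles(**kwargs) -> dict[str, ActivityProfile]:
    """The packaged per-pH activity table (synthetic reconstruction).

    One profile per enzyme of the feast/famine analysis set (the triose
    phosphate isomerase assay is excluded for its inconsistent dilution
    series).  The numbers are a synthetic stand-in consistent with the
    published percent- and fold-change statements, not measured data.
    """
    ref = resources.files("phkin.data") / "activity_profiles_synthetic.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return profiles_from_frame(df, **kwargs)
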