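"""Synthetic study generation with known ground truth.

Everything the pipeline consumes can be generated here: noisy absorbance
progression curves produced by the assay ODE models, pHluorin titration
tables, and feast/famine intracellular pH traces.  The generator's role
is to close the loop: curves generated at a known per-pH capacity must be
recovered by both estimators within their stated tolerances.

Defaults emulate the study conditions: a pH grid from 6.19 to 7.90,
a dilution series of the cell-free extract (coupling enzymes are purified
additions and are *not* diluted), three technical replicates, 10 s
sampling over a 10 min reaction window preceded by a 5 min background
window, and additive Gaussian plate-reader noise of 0.002 AU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .assay import AssayScheme, monitored_trace, simulate_assay
from .calibration import calibration_for, conc_to_abs
from .keq import KeqTable, load_packaged_tables
from .schemes import ENZYMES, at_condition, load_scheme
from .slope import ProgressionCurve

#: assayed pH grid (lowest to highest buffer mixes)
DEFAULT_PH_GRID = (6.19, 6.4, 6.6, 6.8, 7.1, 7.4, 7.6, 7.9)
#: cell-free extract dilution series
DEFAULT_DILUTIONS = (1, 2, 4, 32)
DEFAULT_SIGMA_AU = 0.002
ASSAY_VOLUME_ML = 0.3

#: ground-truth capacity at the reference pH 6.8 (umol/min/mg) and the
#: pH-response shape (optimum, width) per enzyme; shapes emulate the
#: spread of observed profiles (optima across the grid, 0.3-1.7x relative
#: span) while keeping every (pH, dilution) trace measurable
TRUE_PROFILE_PARAMS: dict[str, tuple[float, float, float]] = {
    # enzyme: (capacity at pH 6.8, optimum pH, width)
    "HXK": (0.6, 7.0, 0.6),
    "PGI": (0.3, 7.6, 0.8),
    "PFK": (0.25, 6.9, 0.7),
    "ALD": (0.3, 7.0, 0.7),
    "TPI": (0.6, 7.6, 0.9),
    "GAPDHF": (0.6, 7.9, 0.85),
    "GAPDHR": (0.4, 6.6, 1.0),
    "PGM": (0.6, 7.2, 0.7),
    "ENO": (2.0, 7.5, 0.8),
    "PYK": (0.6, 7.0, 1.5),
    "PDC": (0.6, 6.9, 0.8),
}


def generate_ph_response(
    ph_grid: Sequence[float],
    optimum: float,
    width: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Smooth unimodal Vmax(pH) profile (Gaussian bell in pH).

    ``amplitude`` is the peak value at the optimum; ``width`` -> inf gives
    a flat profile.  log-activity is quadratic in pH, so profiles are
    symmetric about the optimum.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if not np.isfinite(width) or width <= 0:
        return np.full_like(ph, amplitude)
    return amplitude * np.exp(-0.5 * ((ph - optimum) / width) ** 2)


def true_vmax_by_ph(enzyme_id: str, ph_grid: Sequence[float]) -> dict[float, float]:
    """Ground-truth capacity per pH, normalized to the reference value at 6.8."""
    base, opt, width = TRUE_PROFILE_PARAMS[enzyme_id]
    shape = generate_ph_response(ph_grid, opt, width)
    ref = generate_ph_response([6.8], opt, width)[0]
    return {float(ph): float(base * s / ref) for ph, s in zip(ph_grid, shape)}


@dataclass
class StudyDesign:
    """Experimental design of a synthetic study."""

    ph_grid: tuple[float, ...] = DEFAULT_PH_GRID
    dilution_factors: tuple[float, ...] = DEFAULT_DILUTIONS
    replicates: int = 3
    sampling_interval_s: float = 10.0
    reaction_minutes: float = 10.0
    background_minutes: float = 5.0
    sigma_au: float = DEFAULT_SIGMA_AU
    drift_au_per_min: float = 0.0

    def reaction_grid(self) -> np.ndarray:
        dt = self.sampling_interval_s / 60.0
        return np.arange(0.0, self.reaction_minutes + 1e-9, dt)

    def background_grid(self) -> np.ndarray:
        dt = self.sampling_interval_s / 60.0
        return np.arange(0.0, self.background_minutes + 1e-9, dt)


@dataclass
class SyntheticStudy:
    """Generated curves plus the ground truth that produced them."""

    design: StudyDesign
    seed: int
    curves: list[ProgressionCurve]
    truth_vmax: dict[str, dict[float, float]]  # enzyme -> pH -> capacity
    truth_km: dict[str, dict[str, float]]  # enzyme -> reactant -> Km

    def curves_for(self, enzyme_id: str) -> list[ProgressionCurve]:
        return [c for c in self.curves if c.enzyme_id == enzyme_id]


def generate_progression_curves(
    scheme: AssayScheme,
    vmax_by_ph: Mapping[float, float],
    design: StudyDesign,
    seed: int,
    keq_tables: Mapping[str, KeqTable] | None = None,
    km_by_ph: Mapping[float, Mapping[str, float]] | None = None,
) -> list[ProgressionCurve]:
    """Simulate noisy plate-reader traces for one enzyme across the design.

    Per curve: integrate the assay ODEs at the pH/dilution condition,
    convert the monitored species to absorbance through the calibration
    line, and add i.i.d. Gaussian noise.  Background traces are the
    pre-start optical level plus the same linear drift (if any) and noise.
    The same seed reproduces identical curves.
    """
    if keq_tables is None:
        keq_tables = load_packaged_tables()
    rng = np.random.default_rng(seed)
    cal = calibration_for(scheme.monitored_species)
    t_rxn = design.reaction_grid()
    t_bg = design.background_grid()
    curves = []
    for ph in design.ph_grid:
        vmax = float(vmax_by_ph[ph])
        for df in design.dilution_factors:
            inst = at_condition(scheme, ph=ph, dilution_factor=df, test_vmax=vmax)
            if km_by_ph is not None:
                test = inst.test_reaction
                new_km = dict(test.rate_law.km) | dict(km_by_ph[ph])
                law = replace(test.rate_law, km=new_km)
                inst = inst.with_params({test.id: law})
            inst = inst.resolve_keq(keq_tables)
            traj = simulate_assay(inst, times_min=t_rxn)
            mon_umol = monitored_trace(traj, inst) * ASSAY_VOLUME_ML
            signal = conc_to_abs(mon_umol, cal)
            bg_level = conc_to_abs(
                inst.initial_concentrations.get(inst.monitored_species, 0.0)
                * ASSAY_VOLUME_ML, cal)
            for rep in range(1, design.replicates + 1):
                noise_r = rng.normal(0.0, design.sigma_au, len(t_rxn))
                noise_b = rng.normal(0.0, design.sigma_au, len(t_bg))
                drift = design.drift_au_per_min
                curves.append(ProgressionCurve(
                    enzyme_id=scheme.enzyme_id,
                    ph=float(ph),
                    dilution_factor=float(df),
                    replicate=rep,
                    times=t_rxn.copy(),
                    absorbance=signal + drift * t_rxn + noise_r,
                    background=(t_bg.copy(),
                                bg_level + drift * t_bg + noise_b),
                    wavelength=inst.wavelength,
                    direction=inst.direction,
                ))
    return curves


def generate_study(
    seed: int,
    enzymes: Sequence[str] = ENZYMES,
    design: StudyDesign | None = None,
    keq_tables: Mapping[str, KeqTable] | None = None,
) -> SyntheticStudy:
    """Full multi-enzyme synthetic study with stored ground truth.

    Each enzyme gets an independent child seed derived from ``seed`` so
    regeneration is deterministic and enzyme subsets are reproducible.
    """
    if design is None:
        design = StudyDesign()
    if keq_tables is None:
        keq_tables = load_packaged_tables()
    truth_vmax: dict[str, dict[float, float]] = {}
    truth_km: dict[str, dict[str, float]] = {}
    curves: list[ProgressionCurve] = []
    for i, enzyme in enumerate(enzymes):
        scheme = load_scheme(enzyme)
        vmax_by_ph = true_vmax_by_ph(enzyme, design.ph_grid)
        truth_vmax[enzyme] = vmax_by_ph
        truth_km[enzyme] = dict(scheme.test_reaction.rate_law.km)
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                         % (2**31))
        curves.extend(generate_progression_curves(
            scheme, vmax_by_ph, design, child_seed, keq_tables))
    return SyntheticStudy(design=design, seed=seed, curves=curves,
                          truth_vmax=truth_vmax, truth_km=truth_km)


def generate_feast_famine_trace(
    ph_hi: float = 7.1,
    ph_lo: float = 6.4,
    half_cycle_min: float = 5.0,
    tau_min: float = 0.4,
    horizon_min: float = 30.0,
    dt_min: float = 0.05,
    sigma: float = 0.0,
    seed: int | None = None,
):
    """Square-wave cytosolic pH trace with first-order relaxation.

    Starts at the feast level ``ph_hi``; glucose removal at t=0 drives
    relaxation toward ``ph_lo`` with time constant ``tau_min``, switching
    back every ``half_cycle_min``.  ``tau_min=0`` gives an ideal square
    wave.  Returns (times_min, ph) arrays.
    """
    if ph_hi <= ph_lo:
        raise ValueError("ph_hi must exceed ph_lo")
    times = np.arange(0.0, horizon_min + 1e-9, dt_min)
    targets = np.where((times // half_cycle_min).astype(int) % 2 == 0,
                       ph_lo, ph_hi)
    ph = np.empty_like(times)
    current = ph_hi
    for i, (t, target) in enumerate(zip(times, targets)):
        if tau_min <= 0:
            current = target
        elif i > 0:
            current = target + (current - target) * np.exp(-dt_min / tau_min)
        ph[i] = current
    if sigma > 0:
        rng = np.random.default_rng(seed)
        ph = ph + rng.normal(0.0, sigma, len(ph))
    return times, ph


#: default "true" pHluorin response used by the titration generator:
#: pH as a monotone cubic in the excitation ratio R390/470
DEFAULT_PHLUORIN_POLY = (4.0, 1.6, -0.2, 0.05)  # ascending coefficients
DEFAULT_RATIO_RANGE = (0.55, 3.6)


def _poly(r, coeffs):
    return np.polynomial.polynomial.polyval(r, np.asarray(coeffs, dtype=float))


def generate_titration(
    true_poly: Sequence[float] = DEFAULT_PHLUORIN_POLY,
    ph_range: tuple[float, float] = (4.86, 8.41),
    n_points: int = 12,
    sigma_ratio: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """(ratio, pH) titration table from the inverse of the true polynomial.

    Buffer pH values are an even grid over ``ph_range`` (endpoints exact);
    measured ratios are the polynomial's inverse plus optional Gaussian
    noise.  Fewer than 5 points violates the downstream fit contract.
    """
    ph_values = np.linspace(ph_range[0], ph_range[1], n_points)
    lo, hi = DEFAULT_RATIO_RANGE[0] - 1.0, DEFAULT_RATIO_RANGE[1] + 2.0
    ratios = np.array([
        brentq(lambda r, target=p: _poly(r, true_poly) - target, lo, hi)
        for p in ph_values
    ])
    if sigma_ratio > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(0.0, sigma_ratio, len(ratios))
    return np.column_stack([ratios, ph_values])
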