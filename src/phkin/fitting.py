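"""Progression-curve fitting of per-pH enzyme capacities.

The estimator treats one enzyme's full set of progression curves
(pH grid x dilution series x replicates) as a single nonlinear
least-squares problem.  The assay ODE model is simulated per condition
and compared with the measured traces in concentration space (the
absorbance calibration lines are linear, so this equals absorbance-space
SSE up to a constant factor).  The free parameters are

* one Vmax per assayed pH (the quantity of interest), and
* Km values shared across the entire pH range,

both optimized in log space (positivity, scale invariance) with bounds.
An optional Tikhonov-style regularization penalizes deviations of the
fitted Km from its literature reference, cost = SSE + lambda * sum
log^2(Km/Km_ref), for problems with a Vmax–Km dependency (detected as
an unidentifiable Km in the unregularized fit; see ``fit_enzyme``).

The model/results split follows the statsmodels convention:

>>> model = ProgressionFitModel(scheme, curves)          # doctest: +SKIP
>>> res = model.fit()                                    # doctest: +SKIP
>>> res.summary()                                        # doctest: +SKIP

Two hypothesis-comparison analyses are built on top: Keq treated as
pH-dependent versus frozen at the reference pH, and pH-dependent Vmax
(global Km) versus pH-dependent Km (global Vmax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .assay import AssayScheme, NumericalError, monitored_trace, simulate_assay
from .calibration import abs_to_conc, calibration_for
from .keq import KeqTable, load_packaged_tables
from .ratelaw import RateLaw
from .schemes import at_condition
from .slope import EstimationError, ProgressionCurve, estimate_vmax_slope

#: cofactors never chosen as the "start substrate" whose Km is fitted
_COFACTORS = frozenset({"ATP", "ADP", "NAD", "NADH", "NADP", "NADPH"})

#: residual value substituted when the integrator fails at a trial point
_FAILURE_RESIDUAL = 1e3

ASSAY_VOLUME_ML = 0.3


def start_substrate(scheme: AssayScheme) -> str:
    """The test reaction's start chemical (non-cofactor substrate)."""
    subs = scheme.test_reaction.substrates()
    non_cof = [s for s in subs if s not in _COFACTORS]
    return non_cof[0] if non_cof else subs[0]


def informative_substrate(scheme: AssayScheme) -> str:
    """Test-reaction substrate whose Km the curves can actually inform.

    The assays run at substrate saturation, so most Km directions are
    flat; the least-saturated substrate (smallest initial concentration
    to Km ratio, i.e. the one whose depletion bends the curve first) is
    the only one worth freeing.
    """
    test = scheme.test_reaction
    ratios = {
        s: scheme.initial_concentrations.get(s, 0.0) / test.rate_law.km[s]
        for s in test.substrates()
    }
    return min(ratios, key=ratios.get)


@dataclass
class ProgressionFitResults:
    """Estimates, uncertainties and diagnostics from a progression fit."""

    model: "ProgressionFitModel"
    theta: np.ndarray  # log-parameter vector at the optimum
    vmax: dict[float, float]  # pH -> capacity (umol/min/mg)
    vmax_ci: dict[float, float]  # approximate 95% half-widths
    km: dict[str, float]  # fitted Km (mM), shared across pH
    km_ci: dict[str, float]
    sse: float
    sse_by_ph: dict[float, float]
    regularization_penalty: float
    n_iterations: int
    converged: bool
    n_parameters: int
    n_residuals: int
    residuals: np.ndarray = field(repr=False)
    integration_failures: int = 0

    @property
    def cost(self) -> float:
        return self.sse + self.regularization_penalty

    def predict(self, ph: float, times_min=None, dilution_factor: float = 1.0):
        """Simulated progression + reaction-rate curves at a fitted pH.

        Refuses to extrapolate outside the fitted pH set.
        """
        if ph not in self.vmax:
            raise ValueError(
                f"pH {ph} not in fitted set {sorted(self.vmax)}; "
                "no extrapolation"
            )
        inst = self.model._instance(ph, dilution_factor)
        inst = self.model._apply(inst, self.vmax[ph], self.km)
        return simulate_assay(inst, times_min=times_min)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Progression-curve fit: {m.scheme.enzyme_id}",
            f"  layout: {m.layout}, keq_mode: {m.keq_mode}, "
            f"lambda: {m.lam:g}",
            f"  curves: {len(m.curves)}  residuals: {self.n_residuals}  "
            f"parameters: {self.n_parameters}",
            f"  SSE: {self.sse:.6g}  penalty: "
            f"{self.regularization_penalty:.3g}  converged: {self.converged}",
            "",
            "  pH      Vmax [umol/min/mg]   ~95% half-width      SSE(pH)",
        ]
        for ph in sorted(self.vmax):
            lines.append(
                f"  {ph:5.2f}   {self.vmax[ph]:14.5g}   "
                f"{self.vmax_ci.get(ph, float('nan')):14.3g}   "
                f"{self.sse_by_ph.get(ph, float('nan')):10.4g}"
            )
        lines.append("")
        lines.append("  Km [mM], shared across pH (reference):")
        for name in sorted(self.km):
            ref = m.km_reference.get(name, float("nan"))
            lines.append(
                f"    {name:8s} {self.km[name]:10.5g}  "
                f"+/- {self.km_ci.get(name, float('nan')):.3g}  (ref {ref:g})"
            )
        return "\n".join(lines)


class ProgressionFitModel:
    """Maximum-likelihood (SSE) fit of an assay ODE model to progression curves.

    Parameters
    ----------
    scheme : AssayScheme
        Template for the enzyme's assay (pH/dilution instantiated per curve).
    curves : sequence of ProgressionCurve
        All curves for this enzyme; each pH present gets a Vmax parameter.
    keq_tables : mapping reaction -> KeqTable, optional
        Defaults to the packaged tables.
    keq_mode : {"ph_dependent", "fixed_at_reference"}
    fit_km : sequence of species names, optional
        Kms of the test reaction to optimize (shared across pH).  Default:
        the least-saturated substrate only (see
        :func:`informative_substrate`); the remaining reactants are
        saturating or absent and carry no information in these assays.
    lam : float
        Regularization weight on log(Km/Km_ref); 0 disables.
    layout : {"vmax_per_ph", "km_per_ph"}
        The alternative layout fixes a single global Vmax and lets the
        start-substrate Km vary per pH (hypothesis comparison).
    """

    def __init__(
        self,
        scheme: AssayScheme,
        curves: Sequence[ProgressionCurve],
        *,
        keq_tables: Mapping[str, KeqTable] | None = None,
        keq_mode: str = "ph_dependent",
        km_reference: Mapping[str, float] | None = None,
        fit_km: Sequence[str] | None = None,
        lam: float = 0.0,
        layout: str = "vmax_per_ph",
        bounds_factor: float = 1e4,
        reference_ph: float = 6.8,
        rtol: float = 1e-7,
        atol: float = 1e-9,
    ) -> None:
        if layout not in ("vmax_per_ph", "km_per_ph"):
            raise ValueError(f"unknown layout {layout!r}")
        if not curves:
            raise ValueError("no curves")
        self.scheme = scheme
        self.curves = list(curves)
        self.keq_tables = keq_tables if keq_tables is not None else load_packaged_tables()
        self.keq_mode = keq_mode
        self.layout = layout
        self.lam = float(lam)
        self.bounds_factor = float(bounds_factor)
        self.reference_ph = reference_ph
        self.rtol, self.atol = rtol, atol
        self.cal = calibration_for(scheme.monitored_species)
        test_km = scheme.test_reaction.rate_law.km
        self.km_reference = dict(km_reference) if km_reference else dict(test_km)
        self.fit_km = list(fit_km) if fit_km is not None else [informative_substrate(scheme)]
        for name in self.fit_km:
            if name not in test_km:
                raise ValueError(f"{name!r} has no Km in the test rate law")

        self.ph_values = sorted({c.ph for c in self.curves})
        # unique (ph, df) conditions; replicates share one simulation
        self.conditions = sorted({(c.ph, c.dilution_factor) for c in self.curves})
        self._instances = {
            (ph, df): at_condition(scheme, ph=ph, dilution_factor=df)
            .resolve_keq(self.keq_tables, mode=keq_mode, reference_ph=reference_ph)
            for ph, df in self.conditions
        }
        self._measured = {}  # curve index -> mM trace
        for i, c in enumerate(self.curves):
            self._measured[i] = abs_to_conc(c.absorbance, self.cal) / ASSAY_VOLUME_ML
        self.integration_failures = 0

    # -- parameter vector layout --------------------------------------------

    @property
    def n_parameters(self) -> int:
        if self.layout == "vmax_per_ph":
            return len(self.ph_values) + len(self.fit_km)
        return len(self.ph_values) + 1

    def pack(self, vmax_by_ph: Mapping[float, float],
             km: Mapping[str, float]) -> np.ndarray:
        """Log-parameter vector from named values.

        For the ``km_per_ph`` layout, ``km`` maps pH -> start-substrate Km
        and ``vmax_by_ph`` must be constant (its first value is used).
        """
        if self.layout == "vmax_per_ph":
            values = [vmax_by_ph[ph] for ph in self.ph_values]
            values += [km[name] for name in self.fit_km]
        else:
            values = [km[ph] for ph in self.ph_values]
            values.append(vmax_by_ph[self.ph_values[0]])
        return np.log(np.asarray(values, dtype=float))

    def _unpack(self, theta: np.ndarray):
        """theta -> (vmax_by_ph, km_by_ph_or_shared)."""
        n_ph = len(self.ph_values)
        if self.layout == "vmax_per_ph":
            vmax = {ph: float(np.exp(theta[i]))
                    for i, ph in enumerate(self.ph_values)}
            km = {name: float(np.exp(theta[n_ph + j]))
                  for j, name in enumerate(self.fit_km)}
            km_by_ph = {ph: km for ph in self.ph_values}
        else:
            name = self.fit_km[0]
            km_by_ph = {ph: {name: float(np.exp(theta[i]))}
                        for i, ph in enumerate(self.ph_values)}
            v = float(np.exp(theta[n_ph]))
            vmax = {ph: v for ph in self.ph_values}
        return vmax, km_by_ph

    def _instance(self, ph: float, df: float) -> AssayScheme:
        key = (ph, df)
        if key not in self._instances:
            self._instances[key] = (
                at_condition(self.scheme, ph=ph, dilution_factor=df)
                .resolve_keq(self.keq_tables, mode=self.keq_mode,
                             reference_ph=self.reference_ph)
            )
        return self._instances[key]

    def _apply(self, inst: AssayScheme, vmax: float,
               km: Mapping[str, float]) -> AssayScheme:
        test = inst.test_reaction
        new_km = dict(test.rate_law.km)
        for name, value in km.items():
            new_km[name] = value
        law = RateLaw(test.rate_law.form, vmax, new_km, test.rate_law.keq,
                      test.rate_law.vmax_units)
        return inst.with_params({test.id: law})

    # -- residuals and cost ---------------------------------------------------

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Stacked residual vector (mM) plus regularization rows."""
        vmax, km_by_ph = self._unpack(theta)
        sims = {}
        for ph, df in self.conditions:
            inst = self._apply(self._instances[(ph, df)], vmax[ph], km_by_ph[ph])
            grid = None
            for i, c in enumerate(self.curves):
                if c.ph == ph and c.dilution_factor == df:
                    grid = c.times
                    break
            try:
                traj = simulate_assay(inst, times_min=grid,
                                      rtol=self.rtol, atol=self.atol)
                sims[(ph, df)] = monitored_trace(traj, inst)
            except NumericalError:
                self.integration_failures += 1
                sims[(ph, df)] = None
        blocks = []
        for i, c in enumerate(self.curves):
            sim = sims[(c.ph, c.dilution_factor)]
            if sim is None:
                blocks.append(np.full(len(c.times), _FAILURE_RESIDUAL))
            else:
                blocks.append(sim - self._measured[i])
        if self.lam > 0 and self.layout == "vmax_per_ph":
            n_ph = len(self.ph_values)
            for j, name in enumerate(self.fit_km):
                dev = theta[n_ph + j] - np.log(self.km_reference[name])
                blocks.append(np.array([np.sqrt(self.lam) * dev]))
        return np.concatenate(blocks)

    def cost(self, theta: np.ndarray) -> float:
        """SSE + regularization penalty at a log-parameter vector."""
        r = self.residuals(np.asarray(theta, dtype=float))
        return float(np.sum(r**2))

    def cost_from_values(self, vmax_by_ph: Mapping[float, float],
                         km: Mapping[str, float] | None = None) -> float:
        """Cost at named parameter values (convenience wrapper)."""
        km = dict(km) if km else {n: self.km_reference[n] for n in self.fit_km}
        theta = np.log(np.array(
            [vmax_by_ph[ph] for ph in self.ph_values]
            + ([km[n] for n in self.fit_km] if self.layout == "vmax_per_ph"
               else [])
        ))
        if self.layout == "km_per_ph":
            raise NotImplementedError("use the log-vector cost for km_per_ph")
        return self.cost(theta)

    def _jac_sparsity(self) -> np.ndarray:
        rows = []
        n_ph = len(self.ph_values)
        p = self.n_parameters
        for c in self.curves:
            block = np.zeros((len(c.times), p), dtype=bool)
            i_ph = self.ph_values.index(c.ph)
            block[:, i_ph] = True  # per-pH parameter (Vmax or Km)
            block[:, n_ph:] = True  # shared parameters
            rows.append(block)
        if self.lam > 0 and self.layout == "vmax_per_ph":
            for j in range(len(self.fit_km)):
                row = np.zeros((1, p), dtype=bool)
                row[0, n_ph + j] = True
                rows.append(row)
        return np.vstack(rows)

    # -- initialization --------------------------------------------------------

    def initial_theta(self) -> np.ndarray:
        """Slope-based Vmax per pH and literature Km as starting values."""
        init_vmax = {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates = estimate_vmax_slope(
                    self.curves,
                    cal=self.cal,
                    protein=self.scheme.protein * self.scheme.dilution_factor * 60.0,
                    stoich=self.scheme.monitor_stoichiometry,
                )
            for est in estimates:
                if est.value > 0:
                    init_vmax[est.ph] = est.value
        except EstimationError:
            pass
        fallback = self.scheme.test_reaction.rate_law.vmax
        positives = [v for v in init_vmax.values() if v > 0]
        default = float(np.median(positives)) if positives else fallback
        values = [init_vmax.get(ph, default) for ph in self.ph_values]
        if self.layout == "vmax_per_ph":
            values += [self.km_reference[n] for n in self.fit_km]
        else:
            km0 = self.km_reference[self.fit_km[0]]
            values = [km0] * len(self.ph_values) + [float(np.median(values))]
        return np.log(np.asarray(values, dtype=float))

    # -- fitting ----------------------------------------------------------------

    def fit(
        self,
        theta0: np.ndarray | None = None,
        restarts: int = 1,
        seed: int = 0,
        max_nfev: int | None = None,
        compute_ci: bool = True,
    ) -> ProgressionFitResults:
        """Bounded nonlinear least squares in log-parameter space.

        Deterministic for a given problem and seed; ``restarts > 1`` adds
        multistart perturbations of the initial point (recorded seed).
        """
        theta0 = self.initial_theta() if theta0 is None else np.asarray(theta0, float)
        span = np.log(self.bounds_factor)
        lo, hi = theta0 - span, theta0 + span
        sparsity = self._jac_sparsity()
        rng = np.random.default_rng(seed)
        best = None
        for start in range(max(1, restarts)):
            x0 = theta0 if start == 0 else np.clip(
                theta0 + rng.normal(0.0, 0.5, len(theta0)), lo, hi)
            res = least_squares(
                self.residuals, x0, bounds=(lo, hi), method="trf",
                jac_sparsity=sparsity, x_scale=1.0, max_nfev=max_nfev,
            )
            if best is None or res.cost < best.cost:
                best = res
        return self._results(best, compute_ci=compute_ci)

    def _results(self, res, compute_ci: bool = True) -> ProgressionFitResults:
        theta = res.x
        vmax, km_by_ph = self._unpack(theta)
        if self.layout == "vmax_per_ph":
            km = km_by_ph[self.ph_values[0]]
        else:
            km = {f"{self.fit_km[0]}@{ph}": km_by_ph[ph][self.fit_km[0]]
                  for ph in self.ph_values}
        r = res.fun
        n_data = sum(len(c.times) for c in self.curves)
        data_res = r[:n_data]
        penalty = float(np.sum(r[n_data:] ** 2))
        sse = float(np.sum(data_res**2))
        # per-pH SSE decomposition
        sse_by_ph: dict[float, float] = {ph: 0.0 for ph in self.ph_values}
        offset = 0
        for c in self.curves:
            block = data_res[offset:offset + len(c.times)]
            sse_by_ph[c.ph] += float(np.sum(block**2))
            offset += len(c.times)
        # approximate uncertainties from the linearized covariance.  The
        # jacobian is recomputed densely with a step well above the
        # integrator noise floor; the solver's grouped-FD jacobian uses
        # steps near machine precision and misses near-flat directions.
        n, p = len(r), len(theta)
        vmax_ci: dict[float, float] = {}
        km_ci: dict[str, float] = {}
        try:
            if not compute_ci:
                raise np.linalg.LinAlgError
            eps = 1e-4
            cols = []
            for i in range(p):
                step = theta.copy()
                step[i] += eps
                cols.append((self.residuals(step) - r) / eps)
            J = np.column_stack(cols)
            JtJ = J.T @ J
            dof = max(n - p, 1)
            cov = np.linalg.pinv(JtJ) * (2 * res.cost / dof)
            sd_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            n_ph = len(self.ph_values)
            for i, ph in enumerate(self.ph_values):
                scale = (vmax[ph] if self.layout == "vmax_per_ph"
                         else km_by_ph[ph][self.fit_km[0]])
                hw = 1.96 * sd_log[i] * scale
                if self.layout == "vmax_per_ph":
                    vmax_ci[ph] = hw
                else:
                    km_ci[f"{self.fit_km[0]}@{ph}"] = hw
            if self.layout == "vmax_per_ph":
                for j, name in enumerate(self.fit_km):
                    km_ci[name] = 1.96 * sd_log[n_ph + j] * km[name]
            else:
                vmax_ci = {ph: 1.96 * sd_log[n_ph] * vmax[ph]
                           for ph in self.ph_values}
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
        return ProgressionFitResults(
            model=self,
            theta=theta,
            vmax=vmax,
            vmax_ci=vmax_ci,
            km=km,
            km_ci=km_ci,
            sse=sse,
            sse_by_ph=sse_by_ph,
            regularization_penalty=penalty,
            n_iterations=int(res.nfev),
            converged=bool(res.status > 0),
            n_parameters=p,
            n_residuals=n,
            residuals=data_res,
            integration_failures=self.integration_failures,
        )

    # -- identifiability and regularization -------------------------------------

    def fisher_correlation_condition(self, theta: np.ndarray | None = None) -> float:
        """Condition number of the correlation-normalized Fisher matrix.

        Collinearity between Vmax and Km sensitivities (the mutase-type
        pathology) inflates this number; weakly identified but independent
        directions do not.
        """
        theta = self.initial_theta() if theta is None else theta
        eps = 1e-5
        r0 = self.residuals(theta)
        cols = []
        for i in range(len(theta)):
            step = theta.copy()
            step[i] += eps
            cols.append((self.residuals(step) - r0) / eps)
        J = np.column_stack(cols)
        F = J.T @ J
        d = np.sqrt(np.clip(np.diag(F), 1e-300, np.inf))
        C = F / np.outer(d, d)
        return float(np.linalg.cond(C))

    def needs_regularization(self, threshold: float = 1e6) -> bool:
        return self.fisher_correlation_condition() > threshold


def km_identifiable(result: ProgressionFitResults,
                    rel_threshold: float = 0.5) -> bool:
    """Whether the fitted Km is determined by the data.

    Uses the fit's own linearized covariance: the Km is considered
    identifiable when its approximate 95% half-width is below
    ``rel_threshold`` relative to the estimate.  An unidentifiable Km
    signals a Vmax–Km dependency (the mutase-type pathology) and calls
    for regularization toward the literature value.
    """
    for name, value in result.km.items():
        hw = result.km_ci.get(name, np.inf)
        if not np.isfinite(hw) or hw > rel_threshold * abs(value):
            return False
    return True


def select_lambda(
    model: ProgressionFitModel,
    grid: Sequence[float] | None = None,
    holdout_replicate: int | None = None,
    theta0: np.ndarray | None = None,
) -> float:
    """Pick lambda by generalization error on a held-out replicate.

    Fits each candidate weight on all curves except one replicate
    (warm-started from ``theta0``) and scores the unpenalized prediction
    SSE on the held-out curves.  Returns the best lambda.
    """
    if grid is None:
        grid = np.logspace(-4, 5, 10)
    reps = sorted({c.replicate for c in model.curves})
    if holdout_replicate is None:
        holdout_replicate = reps[-1]
    train = [c for c in model.curves if c.replicate != holdout_replicate]
    test = [c for c in model.curves if c.replicate == holdout_replicate]
    if not train or not test:
        raise ValueError("need >= 2 replicates to select lambda")
    holdout = ProgressionFitModel(
        model.scheme, test, keq_tables=model.keq_tables,
        keq_mode=model.keq_mode, km_reference=model.km_reference,
        fit_km=model.fit_km, lam=0.0, layout=model.layout,
    )
    best_lam, best_err = float(grid[0]), np.inf
    warm = theta0
    for lam in grid:
        m = ProgressionFitModel(
            model.scheme, train, keq_tables=model.keq_tables,
            keq_mode=model.keq_mode, km_reference=model.km_reference,
            fit_km=model.fit_km, lam=float(lam), layout=model.layout,
        )
        res = m.fit(theta0=warm, max_nfev=40, compute_ci=False)
        warm = res.theta
        err = holdout.cost(np.concatenate([
            [np.log(res.vmax[ph]) for ph in holdout.ph_values],
            [np.log(res.km[n]) for n in holdout.fit_km],
        ]))
        if err < best_err:
            best_lam, best_err = float(lam), err
    return best_lam


def fit_enzyme(
    scheme: AssayScheme,
    curves: Sequence[ProgressionCurve],
    lam: float | str = 0.0,
    **kwargs,
) -> ProgressionFitResults:
    """Convenience driver implementing the default lambda policy.

    ``lam='auto'``: fit unregularized first; when the fitted Km is not
    identifiable from the data (see :func:`km_identifiable`, the
    mutase-type Vmax–Km dependency), choose a weight by the held-out
    replicate sweep and refit warm-started.  Otherwise lambda = 0.
    """
    if lam == "auto":
        model0 = ProgressionFitModel(scheme, curves, lam=0.0, **kwargs)
        res0 = model0.fit()
        if km_identifiable(res0):
            return res0
        lam_value = select_lambda(model0, theta0=res0.theta)
        model = ProgressionFitModel(scheme, curves, lam=lam_value, **kwargs)
        return model.fit(theta0=res0.theta)
    model = ProgressionFitModel(scheme, curves, lam=float(lam), **kwargs)
    return model.fit()


def compare_keq_modes(
    scheme: AssayScheme,
    curves: Sequence[ProgressionCurve],
    **kwargs,
) -> dict:
    """Refit with pH-dependent vs reference-frozen Keq on identical data.

    Returns per-pH relative Vmax differences and their maximum.
    """
    res_ph = ProgressionFitModel(scheme, curves, keq_mode="ph_dependent",
                                 **kwargs).fit()
    res_fix = ProgressionFitModel(scheme, curves, keq_mode="fixed_at_reference",
                                  **kwargs).fit()
    rel = {
        ph: abs(res_ph.vmax[ph] - res_fix.vmax[ph]) / res_ph.vmax[ph]
        for ph in res_ph.vmax
    }
    return {
        "vmax_ph_dependent": res_ph.vmax,
        "vmax_fixed": res_fix.vmax,
        "relative_difference": rel,
        "max_relative_difference": max(rel.values()),
    }


def compare_ph_dependence(
    scheme: AssayScheme,
    curves: Sequence[ProgressionCurve],
    **kwargs,
) -> dict:
    """pH-dependent Vmax (global Km) vs pH-dependent Km (global Vmax).

    Both layouts have equal parameter counts (n_pH + 1); raw total SSEs
    are compared without information-criterion correction.
    """
    res_a = ProgressionFitModel(scheme, curves, layout="vmax_per_ph",
                                **kwargs).fit()
    res_b = ProgressionFitModel(scheme, curves, layout="km_per_ph",
                                **kwargs).fit()
    return {
        "sse_vmax_varying": res_a.sse,
        "sse_km_varying": res_b.sse,
        "n_params_vmax_varying": res_a.n_parameters,
        "n_params_km_varying": res_b.n_parameters,
        "winner": ("vmax_varying" if res_a.sse < res_b.sse else "km_varying"),
        "results_vmax_varying": res_a,
        "results_km_varying": res_b,
    }
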