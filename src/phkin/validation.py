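"""Independent numerical checks for the assay simulations.

Two orthogonal oracles validate :func:`phkin.assay.simulate_assay`:

* :func:`derivatives_by_name` re-assembles the ODE right-hand side
  naively (name-keyed dictionaries, per-reaction :func:`phkin.ratelaw.rate`
  calls) and is compared pointwise against the compiled right-hand side,
  validating the ODE assembly.
* :func:`simulate_fixed_step` integrates with a classical fixed-step RK4
  scheme instead of the adaptive stiff solver, validating the
  integration.  The step must resolve the fastest coupling relaxation;
  :func:`stable_step` derives it from the explicit-stability bound
  dt < 2.8 / max_r (Vmax_r / min Km_r) with a safety factor.
"""

from __future__ import annotations

import numpy as np

from .assay import AssayScheme, Trajectory, build_ode_system, initial_state
from .ratelaw import rate


def derivatives_by_name(scheme: AssayScheme, conc: dict[str, float]) -> dict[str, float]:
    """Naive name-keyed evaluation of the assay derivatives (mM/min)."""
    clamped = {s: (c if c > 0.0 else 0.0) for s, c in conc.items()}
    dydt = {s: 0.0 for s in conc}
    for rxn in scheme.reactions:
        v = rate(rxn, clamped, vmax_mm_per_min=scheme.effective_vmax(rxn))
        for s, coeff in rxn.stoichiometry.items():
            dydt[s] += coeff * v
    return dydt


def stable_step(scheme: AssayScheme, safety: float = 0.35) -> float:
    """Fixed step (min) inside the RK4 stability region for this scheme.

    The fastest local relaxation rate of a saturable reaction is bounded
    by Vmax / min(Km); RK4 is stable for rate * dt < ~2.8.
    """
    fastest = 0.0
    for rxn in scheme.reactions:
        vmax = scheme.effective_vmax(rxn)
        km_min = min(rxn.rate_law.km.values())
        fastest = max(fastest, vmax / km_min)
    if fastest == 0.0:
        return 1e-3
    # cap: even non-stiff schemes need enough steps for RK4 accuracy
    return min(safety * 2.8 / fastest, 1e-3)


def simulate_fixed_step(
    scheme: AssayScheme,
    times_min,
    dt: float | None = None,
) -> Trajectory:
    """Classical RK4 integration of the assay at fixed step ``dt`` (min).

    Output is sampled at ``times_min``; when ``dt`` is omitted it is taken
    from :func:`stable_step`.  Deliberately naive: no error control, no
    stiffness handling beyond the stability-bounded step.
    """
    times_min = np.asarray(times_min, dtype=float)
    if dt is None:
        dt = stable_step(scheme)
    f, names = build_ode_system(scheme)
    y, _ = initial_state(scheme)
    out = np.empty((len(times_min), len(names)))
    out[0] = y
    t = times_min[0]
    for k in range(1, len(times_min)):
        span = times_min[k] - t
        n_sub = max(1, int(np.ceil(span / dt - 1e-12)))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = f(y, t)
            k2 = f(y + 0.5 * h * k1, t)
            k3 = f(y + 0.5 * h * k2, t)
            k4 = f(y + h * k3, t)
            y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        t = times_min[k]
        out[k] = y
    return Trajectory(
        times=times_min,
        concentrations={s: out[:, i] for i, s in enumerate(names)},
        fluxes={},
    )


def max_relative_deviation(a: Trajectory, b: Trajectory) -> float:
    """Worst per-species deviation, relative to that species' scale."""
    worst = 0.0
    for s, series in a.concentrations.items():
        other = b.concentrations[s]
        scale = max(np.max(np.abs(series)), np.max(np.abs(other)), 1e-9)
        worst = max(worst, float(np.max(np.abs(series - other)) / scale))
    return worst
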