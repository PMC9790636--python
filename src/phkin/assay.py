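"""Assay schemes and ODE simulation of optical progression curves.

An :class:`AssayScheme` is the executable description of one plate-reader
enzyme assay: the test reaction, any surplus coupling reactions, the
initial concentrations of the reaction mix, and which optical species is
monitored (NADH/NADPH at 340 nm or PEP at 240 nm).  The coupled system
is integrated as a set of concatenated ODEs

    dc_i/dt = sum_r  n_{ir} * v_r(c)

with reversible Michaelis–Menten rates v_r.  Coupling enzymes are
purified additions in large surplus (Vmax inflated by ``coupling_surplus``,
default 1e3, over literature values) so that the observed optical rate
is controlled by the test enzyme.

State is in mM, time in minutes.  Integration uses a stiff-capable
solver (LSODA) at rtol 1e-8 / atol 1e-10 mM with dense output on the
experimental sampling grid; the surplus coupling rates make these
systems moderately stiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.linalg import null_space

from .ratelaw import (
    ConfigurationError,
    RateLaw,
    ReactionSpec,
    VmaxUnits,
    _evaluate,
    rate,
)

#: species never included in conservation checks (open sinks / solvent)
DEFAULT_SINKS = frozenset({"CO2", "EtOH", "H2O"})


class NumericalError(RuntimeError):
    """Integration failed or produced unphysical concentrations."""


@dataclass
class AssayScheme:
    """One kinetic assay: test reaction + coupling cascade + mix composition.

    ``protein`` is mg total extract protein per mL of assay *at this
    dilution factor*; it converts the test enzyme's per-mg capacity to an
    absolute in-assay rate.  ``monitor_stoichiometry`` is the number of
    monitored molecules turned over per test-reaction turnover (2 for the
    PGI/PFK/ALD assays where one hexose phosphate yields two trioses).
    """

    enzyme_id: str
    reactions: list[ReactionSpec]
    initial_concentrations: dict[str, float]
    monitored_species: str
    wavelength: float = 340.0
    direction: str = "decrease"  # of the monitored optical signal
    monitor_stoichiometry: int = 1
    ph: float = 6.8
    protein: float = 0.05  # mg/mL in assay
    dilution_factor: float = 1.0
    coupling_surplus: float = 1e3
    non_conserved: frozenset[str] = field(default_factory=lambda: DEFAULT_SINKS)

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ConfigurationError(f"direction must be increase|decrease")
        tests = [r for r in self.reactions if r.role == "test"]
        if len(tests) != 1:
            raise ConfigurationError(
                f"{self.enzyme_id}: exactly one test reaction required, got {len(tests)}"
            )
        for s, c in self.initial_concentrations.items():
            if c < 0:
                raise ConfigurationError(f"negative initial concentration {s}={c}")
        if self.monitored_species not in self.species():
            raise ConfigurationError(
                f"{self.enzyme_id}: monitored species {self.monitored_species!r} "
                "not in scheme"
            )
        self.non_conserved = frozenset(self.non_conserved)

    # -- structure ---------------------------------------------------------

    @property
    def test_reaction(self) -> ReactionSpec:
        return next(r for r in self.reactions if r.role == "test")

    def species(self) -> list[str]:
        """All species, in stable order: initial concentrations first."""
        names = list(self.initial_concentrations)
        for rxn in self.reactions:
            for s in rxn.stoichiometry:
                if s not in names:
                    names.append(s)
        return names

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(n_species x n_reactions) matrix and its species ordering."""
        names = self.species()
        mat = np.zeros((len(names), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, c in rxn.stoichiometry.items():
                mat[names.index(s), j] = c
        return mat, names

    def conserved_moieties(self) -> tuple[np.ndarray, list[str]]:
        """Left null-space basis of the stoichiometric matrix.

        Rows of the returned array are conservation vectors over the
        returned species list (sinks excluded); each corresponding linear
        combination of concentrations is constant along any trajectory.
        """
        mat, names = self.stoichiometric_matrix()
        keep = [i for i, s in enumerate(names) if s not in self.non_conserved]
        basis = null_space(mat[keep, :].T)
        return basis.T, [names[i] for i in keep]

    def effective_vmax(self, reaction: ReactionSpec) -> float:
        """Absolute Vmax (mM/min) of one reaction in this assay instance."""
        law = reaction.rate_law
        v = law.vmax
        if law.vmax_units is VmaxUnits.PER_MG_PROTEIN:
            v = v * self.protein
        if reaction.role == "coupling":
            v = v * self.coupling_surplus
        return v

    # -- Keq handling ------------------------------------------------------

    def resolve_keq(self, keq_tables, mode: str = "ph_dependent",
                    reference_ph: float = 6.8) -> "AssayScheme":
        """Replace tabular Keq references by numbers for this scheme's pH.

        ``mode='ph_dependent'`` evaluates each referenced table at
        ``self.ph``; ``mode='fixed_at_reference'`` evaluates at
        ``reference_ph`` regardless of the assay pH.
        """
        if mode not in ("ph_dependent", "fixed_at_reference"):
            raise ConfigurationError(f"unknown keq mode {mode!r}")
        ph = self.ph if mode == "ph_dependent" else reference_ph
        new_reactions = []
        for rxn in self.reactions:
            law = rxn.rate_law
            if isinstance(law.keq, str):
                law = law.resolved(keq_tables[law.keq].at_ph(ph))
                rxn = replace(rxn, rate_law=law, stoichiometry=dict(rxn.stoichiometry))
            new_reactions.append(rxn)
        return replace(
            self,
            reactions=new_reactions,
            initial_concentrations=dict(self.initial_concentrations),
        )

    def with_params(self, params: Mapping[str, RateLaw] | None) -> "AssayScheme":
        """Copy with selected reactions' rate laws replaced (keyed by id)."""
        if not params:
            return self
        new_reactions = []
        for rxn in self.reactions:
            if rxn.id in params:
                rxn = replace(rxn, rate_law=params[rxn.id],
                              stoichiometry=dict(rxn.stoichiometry))
            new_reactions.append(rxn)
        return replace(
            self,
            reactions=new_reactions,
            initial_concentrations=dict(self.initial_concentrations),
        )


@dataclass
class Trajectory:
    """Simulated assay time course: concentrations and per-reaction fluxes."""

    times: np.ndarray  # min
    concentrations: dict[str, np.ndarray]  # mM
    fluxes: dict[str, np.ndarray]  # mM/min

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: columns time_s, species, concentration_mM."""
        rows = []
        for species, conc in self.concentrations.items():
            rows.append(pd.DataFrame({
                "time_s": self.times * 60.0,
                "species": species,
                "concentration_mM": conc,
            }))
        return pd.concat(rows, ignore_index=True)


def build_ode_system(
    scheme: AssayScheme,
    params: Mapping[str, RateLaw] | None = None,
) -> tuple[Callable[[np.ndarray, float], np.ndarray], list[str]]:
    """Compile the scheme into a derivative function ``f(y, t) -> dy/dt``.

    The derivative of each species is the stoichiometry-weighted sum of
    reaction rates; species absent from every stoichiometry are constant.
    Returns the function together with the species ordering of the state
    vector.  Small negative excursions of the integrator are clamped to
    zero inside the rate evaluation only.
    """
    scheme = scheme.with_params(params)
    names = scheme.species()
    index = {s: i for i, s in enumerate(names)}
    compiled = []  # (form, vmax, keq, sub_idx, prod_idx, ks, kp, [(i, coeff)])
    for rxn in scheme.reactions:
        law = rxn.rate_law
        if isinstance(law.keq, str):
            raise ConfigurationError(
                f"{scheme.enzyme_id}/{rxn.id}: Keq table reference {law.keq!r} "
                "unresolved; call resolve_keq first"
            )
        subs, prods = rxn.substrates(), rxn.products()
        compiled.append((
            law.form,
            scheme.effective_vmax(rxn),
            float(law.keq),
            [index[s] for s in subs],
            [index[s] for s in prods],
            [law.km[s] for s in subs],
            [law.km[s] for s in prods],
            [(index[s], float(c)) for s, c in rxn.stoichiometry.items()],
        ))
    for rxn in scheme.reactions:
        for s in rxn.rate_law.km:
            if s not in index:
                raise ConfigurationError(
                    f"{scheme.enzyme_id}/{rxn.id}: species {s!r} appears in a "
                    "rate law but is not part of the assay state (no initial "
                    "concentration and no stoichiometric entry)"
                )
    n = len(names)

    def f(y: np.ndarray, t: float) -> np.ndarray:
        dy = np.zeros(n)
        for form, vmax, keq, si, pi, ks, kp, stoich in compiled:
            s = [y[i] if y[i] > 0.0 else 0.0 for i in si]
            p = [y[i] if y[i] > 0.0 else 0.0 for i in pi]
            v = _evaluate(form, vmax, keq, s, p, ks, kp)
            for i, coeff in stoich:
                dy[i] += coeff * v
        return dy

    return f, names


def initial_state(scheme: AssayScheme) -> tuple[np.ndarray, list[str]]:
    names = scheme.species()
    y0 = np.array([scheme.initial_concentrations.get(s, 0.0) for s in names])
    return y0, names


def simulate_assay(
    scheme: AssayScheme,
    params: Mapping[str, RateLaw] | None = None,
    times_min: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    negative_tolerance: float = 1e-6,
) -> Trajectory:
    """Integrate the assay ODEs on ``times_min`` (increasing, from 0).

    Raises :class:`NumericalError` on integrator failure or negative
    concentrations beyond ``negative_tolerance`` mM.
    """
    if times_min is None:
        times_min = np.arange(0.0, 10.0 + 1e-9, 1.0 / 6.0)
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] != 0.0:
        raise ValueError("time grid must be increasing and start at 0")
    scheme = scheme.with_params(params)
    f, names = build_ode_system(scheme)
    y0, _ = initial_state(scheme)
    y, info = odeint(f, y0, t, rtol=rtol, atol=atol, mxstep=100000,
                     full_output=True)
    if info["message"] != "Integration successful.":
        raise NumericalError(
            f"integration failed for scheme {scheme.enzyme_id} at pH "
            f"{scheme.ph}: {info['message']}"
        )
    if np.min(y) < -negative_tolerance:
        raise NumericalError(
            f"negative concentrations ({np.min(y):.3g} mM) for scheme "
            f"{scheme.enzyme_id} at pH {scheme.ph}"
        )
    conc = {s: y[:, i] for i, s in enumerate(names)}
    fluxes = {}
    for rxn in scheme.reactions:
        vmax = scheme.effective_vmax(rxn)
        law = rxn.rate_law
        si = [names.index(s) for s in rxn.substrates()]
        pi = [names.index(s) for s in rxn.products()]
        ks = [law.km[s] for s in rxn.substrates()]
        kp = [law.km[s] for s in rxn.products()]
        flux = np.empty(len(t))
        for k in range(len(t)):
            s = [max(y[k, i], 0.0) for i in si]
            p = [max(y[k, i], 0.0) for i in pi]
            flux[k] = _evaluate(law.form, vmax, float(law.keq), s, p, ks, kp)
        fluxes[rxn.id] = flux
    return Trajectory(times=t, concentrations=conc, fluxes=fluxes)


def monitored_trace(trajectory: Trajectory, scheme: AssayScheme) -> np.ndarray:
    """Monitored-species concentration time series (mM)."""
    return trajectory.concentrations[scheme.monitored_species]


def check_coupling_excess(
    scheme: AssayScheme,
    params: Mapping[str, RateLaw] | None = None,
    horizon_min: float = 1.0,
) -> float:
    """Flux-control score of the coupling cascade, in [0, 1].

    Ratio of the observed monitored-species rate (the peak
    direction-signed ODE derivative of the monitored species over a short
    simulation, i.e. once the coupling intermediates have reached
    quasi-steady state) to ``monitor_stoichiometry`` times the
    test-reaction flux at the initial concentrations.  Direct assays score
    1 by construction (the peak is at t=0); a broken cascade scores 0.
    """
    scheme = scheme.with_params(params)
    test = scheme.test_reaction
    v0 = rate(test, scheme.initial_concentrations
              | {s: 0.0 for s in scheme.species()
                 if s not in scheme.initial_concentrations},
              vmax_mm_per_min=scheme.effective_vmax(test))
    if v0 == 0:
        return 0.0
    grid = np.linspace(0.0, horizon_min, 601)
    traj = simulate_assay(scheme, times_min=grid)
    mon_rate = np.zeros(len(grid))
    for rxn in scheme.reactions:
        coeff = rxn.stoichiometry.get(scheme.monitored_species, 0)
        if coeff:
            mon_rate += coeff * traj.fluxes[rxn.id]
    if scheme.direction == "decrease":
        mon_rate = -mon_rate
    observed = float(np.max(mon_rate))
    score = observed / (scheme.monitor_stoichiometry * abs(v0))
    return float(min(max(score, 0.0), 1.0))


def conservation_residual(trajectory: Trajectory, scheme: AssayScheme) -> float:
    """Worst relative drift of any conserved moiety along the trajectory."""
    basis, names = scheme.conserved_moieties()
    if basis.size == 0:
        return 0.0
    arr = np.vstack([trajectory.concentrations[s] for s in names])
    worst = 0.0
    for vec in basis:
        series = vec @ arr
        scale = max(np.max(np.abs(series)), 1e-12)
        worst = max(worst, float(np.ptp(series) / scale))
    return worst
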