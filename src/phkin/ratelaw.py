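"""Reversible Michaelis–Menten rate laws for the in vitro assay reactions.

Each enzymatic step in an assay is described by a reversible
Michaelis–Menten law parameterized by Vmax, one Km per saturating
reactant, and an equilibrium constant Keq.  Three functional forms cover
every reaction occurring in the coupled and direct assays:

uni-uni   v = Vmax * (S - P/Keq)/Km_S / (1 + S/Km_S + P/Km_P)
bi-bi     v = Vmax * (A*B - P*Q/Keq)/(Km_A*Km_B)
               / ((1 + A/Km_A + P/Km_P) * (1 + B/Km_B + Q/Km_Q))
uni-bi    v = Vmax * (S - P*Q/Keq)/Km_S
               / (1/Km? ... see below)

The uni-bi form (needed for aldolase, one hexose substrate cleaved into
two trioses) uses the additive site denominator
``(1 + S/Km_S) + (1 + P/Km_P)*(1 + Q/Km_Q) - 1`` which reduces to the
uni-uni denominator when the second product is absent.  All three forms
collapse to irreversible Michaelis–Menten as Keq -> inf.

Species such as water, inorganic phosphate, protons, CO2 and ethanol are
non-saturating under assay conditions and are simply excluded from the
rate law (they carry no Km entry).

Units: concentrations in mM, rates in mM/min.  Vmax is stored either as
an absolute in-assay rate (mM/min; purified coupling enzymes, given as
U/mL of assay) or per mg of extract protein (umol/min/mg; the test
enzyme), in which case the assay's protein concentration converts it to
mM/min at simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping


class RateLawForm(str, Enum):
    UNI_UNI_REVERSIBLE = "uni_uni_reversible"
    BI_BI_REVERSIBLE = "bi_bi_reversible"
    UNI_BI_REVERSIBLE = "uni_bi_reversible"


class VmaxUnits(str, Enum):
    #: umol/min per mg extract protein; scaled by assay protein concentration
    PER_MG_PROTEIN = "per_mg_protein"
    #: absolute mM/min in the assay (purified coupling enzymes, U/mL)
    MM_PER_MIN = "mM_per_min"


class ConfigurationError(ValueError):
    """An assay or rate-law definition violates its contract."""


#: expected (n_substrates, n_products) per form
_FORM_ARITY = {
    RateLawForm.UNI_UNI_REVERSIBLE: (1, 1),
    RateLawForm.BI_BI_REVERSIBLE: (2, 2),
    RateLawForm.UNI_BI_REVERSIBLE: (1, 2),
}


@dataclass
class RateLaw:
    """Reversible Michaelis–Menten parameterization of one reaction.

    Parameters
    ----------
    form : RateLawForm
        Kinetic form; must match the reaction's stoichiometric arity
        after exclusion of non-saturating species.
    vmax : float
        Maximal rate, >= 0.  Interpreted according to ``vmax_units``.
    km : mapping of species name -> Km (mM), all > 0
        One entry per saturating reactant.
    keq : float or str
        Equilibrium constant (> 0), or the name of a reaction in a
        pH-dependent Keq table collection, resolved when an assay scheme
        is instantiated at a given pH.
    vmax_units : VmaxUnits
    """

    form: RateLawForm
    vmax: float
    km: dict[str, float]
    keq: float | str
    vmax_units: VmaxUnits = VmaxUnits.MM_PER_MIN

    def __post_init__(self) -> None:
        self.form = RateLawForm(self.form)
        self.vmax_units = VmaxUnits(self.vmax_units)
        if self.vmax < 0:
            raise ConfigurationError(f"Vmax must be >= 0, got {self.vmax}")
        for name, value in self.km.items():
            if not value > 0:
                raise ConfigurationError(f"Km[{name}] must be > 0, got {value}")
        if not isinstance(self.keq, str) and not self.keq > 0:
            raise ConfigurationError(f"Keq must be > 0, got {self.keq}")

    def resolved(self, keq_value: float) -> "RateLaw":
        """Copy of this law with a concrete numeric Keq."""
        return replace(self, keq=float(keq_value), km=dict(self.km))


@dataclass
class ReactionSpec:
    """One reaction of an assay scheme.

    ``stoichiometry`` maps species name -> signed integer coefficient
    (products positive).  ``non_saturating`` lists species that appear
    in the stoichiometry but are excluded from the rate law (and, for
    sinks like CO2/ethanol, from conservation checks).
    """

    id: str
    stoichiometry: dict[str, int]
    rate_law: RateLaw
    role: str = "test"  # "test" | "coupling"
    non_saturating: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.role not in ("test", "coupling"):
            raise ConfigurationError(f"role must be test|coupling, got {self.role!r}")
        self.non_saturating = tuple(self.non_saturating)
        subs, prods = self.substrates(), self.products()
        arity = _FORM_ARITY[self.rate_law.form]
        if (len(subs), len(prods)) != arity:
            raise ConfigurationError(
                f"reaction {self.id!r}: form {self.rate_law.form.value} expects "
                f"{arity} (substrates, products), got ({len(subs)}, {len(prods)})"
            )
        missing = [s for s in subs + prods if s not in self.rate_law.km]
        if missing:
            raise ConfigurationError(
                f"reaction {self.id!r}: missing Km for stoichiometric "
                f"reactant(s) {missing}; flag as non_saturating to exclude"
            )

    def substrates(self) -> list[str]:
        return [
            s
            for s, c in self.stoichiometry.items()
            if c < 0 and s not in self.non_saturating
        ]

    def products(self) -> list[str]:
        return [
            s
            for s, c in self.stoichiometry.items()
            if c > 0 and s not in self.non_saturating
        ]


def rate(
    reaction: ReactionSpec,
    concentrations: Mapping[str, float],
    *,
    vmax_mm_per_min: float | None = None,
) -> float:
    """Net rate (mM/min) of ``reaction`` at the given concentrations.

    Positive in the forward direction of the written stoichiometry.
    ``vmax_mm_per_min`` overrides the rate law's Vmax with an already
    protein-converted absolute value (used by the ODE assembly; when
    omitted the law's Vmax is used as-is and must be in mM/min).
    """
    law = reaction.rate_law
    if isinstance(law.keq, str):
        raise ConfigurationError(
            f"reaction {reaction.id!r}: Keq reference {law.keq!r} not resolved"
        )
    vmax = law.vmax if vmax_mm_per_min is None else vmax_mm_per_min
    subs = reaction.substrates()
    prods = reaction.products()
    try:
        s = [concentrations[name] for name in subs]
        p = [concentrations[name] for name in prods]
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ConfigurationError(f"missing concentration for {exc}") from exc
    for name, c in zip(subs + prods, s + p):
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
    kms = law.km
    ks = [kms[name] for name in subs]
    kp = [kms[name] for name in prods]
    return _evaluate(law.form, vmax, law.keq, s, p, ks, kp)


def _evaluate(form, vmax, keq, s, p, ks, kp):
    """Scalar evaluation shared by `rate` and the compiled ODE right-hand side."""
    if form is RateLawForm.UNI_UNI_REVERSIBLE:
        num = vmax * (s[0] - p[0] / keq) / ks[0]
        den = 1.0 + s[0] / ks[0] + p[0] / kp[0]
    elif form is RateLawForm.BI_BI_REVERSIBLE:
        num = vmax * (s[0] * s[1] - p[0] * p[1] / keq) / (ks[0] * ks[1])
        den = (1.0 + s[0] / ks[0] + p[0] / kp[0]) * (1.0 + s[1] / ks[1] + p[1] / kp[1])
    else:  # UNI_BI_REVERSIBLE
        num = vmax * (s[0] - p[0] * p[1] / keq) / ks[0]
        den = (1.0 + s[0] / ks[0]) + (1.0 + p[0] / kp[0]) * (1.0 + p[1] / kp[1]) - 1.0
    return num / den
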