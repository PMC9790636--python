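"""Loading and serialization of assay schemes.

Eleven assay schemes ship with the package, one per measured enzyme
activity: HXK, PGI, PFK, ALD, TPI, GAPDHF, GAPDHR, PGM, ENO, PYK, PDC.
Compositions follow the published reaction mixes; coupling enzymes carry
their printed U/mL additions as literature Vmax, inflated by the scheme's
surplus factor at simulation time.  Test-reaction Keq entries are string
references into the packaged Keq(pH) tables (except GAPDHR, whose lumped
single-ODE model keeps a fixed Keq).
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import yaml

from .assay import AssayScheme
from .ratelaw import RateLaw, ReactionSpec

ENZYMES = ("HXK", "PGI", "PFK", "ALD", "TPI", "GAPDHF", "GAPDHR",
           "PGM", "ENO", "PYK", "PDC")

#: enzymes included in Fig-9-style transition summaries (TPI is excluded
#: from the activity table, mirroring its inconsistent dilution series)
PROFILE_ENZYMES = tuple(e for e in ENZYMES if e != "TPI")


def scheme_from_dict(data: dict) -> AssayScheme:
    reactions = [
        ReactionSpec(
            id=r["id"],
            stoichiometry={k: int(v) for k, v in r["stoichiometry"].items()},
            rate_law=RateLaw(
                form=r["rate_law"]["form"],
                vmax=float(r["rate_law"]["vmax"]),
                km={k: float(v) for k, v in r["rate_law"]["km"].items()},
                keq=(r["rate_law"]["keq"] if isinstance(r["rate_law"]["keq"], str)
                     else float(r["rate_law"]["keq"])),
                vmax_units=r["rate_law"].get("vmax_units", "mM_per_min"),
            ),
            role=r.get("role", "test"),
            non_saturating=tuple(r.get("non_saturating", ())),
        )
        for r in data["reactions"]
    ]
    return AssayScheme(
        enzyme_id=data["enzyme_id"],
        reactions=reactions,
        initial_concentrations={k: float(v)
                                for k, v in data["initial_concentrations"].items()},
        monitored_species=data["monitored_species"],
        wavelength=float(data.get("wavelength", 340)),
        direction=data.get("direction", "decrease"),
        monitor_stoichiometry=int(data.get("monitor_stoichiometry", 1)),
        ph=float(data.get("ph", 6.8)),
        protein=float(data.get("protein", 0.1)),
        dilution_factor=float(data.get("dilution_factor", 1)),
        coupling_surplus=float(data.get("coupling_surplus", 1e3)),
    )


def scheme_to_dict(scheme: AssayScheme) -> dict:
    return {
        "enzyme_id": scheme.enzyme_id,
        "monitored_species": scheme.monitored_species,
        "wavelength": scheme.wavelength,
        "direction": scheme.direction,
        "monitor_stoichiometry": scheme.monitor_stoichiometry,
        "initial_concentrations": dict(scheme.initial_concentrations),
        "ph": scheme.ph,
        "protein": scheme.protein,
        "dilution_factor": scheme.dilution_factor,
        "coupling_surplus": scheme.coupling_surplus,
        "reactions": [
            {
                "id": r.id,
                "role": r.role,
                "stoichiometry": dict(r.stoichiometry),
                "non_saturating": list(r.non_saturating),
                "rate_law": {
                    "form": r.rate_law.form.value,
                    "vmax": r.rate_law.vmax,
                    "km": dict(r.rate_law.km),
                    "keq": r.rate_law.keq,
                    "vmax_units": r.rate_law.vmax_units.value,
                },
            }
            for r in scheme.reactions
        ],
    }


def read_scheme(path: str | Path) -> AssayScheme:
    with open(path) as fh:
        return scheme_from_dict(yaml.safe_load(fh))


def write_scheme(scheme: AssayScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme_to_dict(scheme), fh, sort_keys=False)


def load_scheme(enzyme_id: str) -> AssayScheme:
    """Load one of the packaged assay schemes by enzyme id."""
    if enzyme_id not in ENZYMES:
        raise KeyError(f"no packaged scheme for {enzyme_id!r}; have {ENZYMES}")
    ref = resources.files("phkin.data") / "schemes" / f"{enzyme_id}.yaml"
    with resources.as_file(ref) as path:
        return read_scheme(path)


def load_all_schemes() -> dict[str, AssayScheme]:
    return {e: load_scheme(e) for e in ENZYMES}


def gapdhr_explicit_pgk() -> AssayScheme:
    """GAPDH-reverse assay with the kinase pre-step modeled explicitly.

    The packaged GAPDHR scheme lumps the surplus-PGK conversion of 3PG
    into a quasi-steady 1,3BPG pool (single ODE).  This variant instead
    concatenates the PGK reaction (3PG + ATP -> 1,3BPG + ADP, the
    unfavorable direction of the physiological step), so 1,3BPG is
    maintained at its small kinase-equilibrium level.  Useful for
    checking how sensitive estimates are to the lumping assumption.
    """
    scheme = load_scheme("GAPDHR")
    pgk_rev = ReactionSpec(
        id="pgk_rev", role="coupling",
        stoichiometry={"P3G": -1, "ATP": -1, "BPG": 1, "ADP": 1},
        rate_law=RateLaw("bi_bi_reversible", 22.5,
                         {"P3G": 0.53, "ATP": 0.3, "BPG": 0.05, "ADP": 0.2},
                         1.0 / 3200.0),
    )
    reactions = [pgk_rev] + [
        replace(r, stoichiometry=dict(r.stoichiometry),
                rate_law=replace(r.rate_law, km=dict(r.rate_law.km)))
        for r in scheme.reactions
    ]
    return replace(scheme, reactions=reactions,
                   initial_concentrations={"P3G": 5.0, "ATP": 1.0,
                                           "NADH": 0.15})


def at_condition(scheme: AssayScheme, ph: float | None = None,
                 dilution_factor: float | None = None,
                 test_vmax: float | None = None) -> AssayScheme:
    """Instantiate a scheme template at a pH / dilution / test capacity.

    Dilution scales the extract protein concentration (coupling enzymes
    are purified additions and are not diluted).  ``test_vmax`` replaces
    the test reaction's per-mg capacity.
    """
    out = scheme
    if ph is not None:
        out = replace(out, ph=float(ph))
    if dilution_factor is not None:
        base_df = out.dilution_factor
        out = replace(out, dilution_factor=float(dilution_factor),
                      protein=out.protein * base_df / float(dilution_factor))
    if test_vmax is not None:
        test = out.test_reaction
        law = replace(test.rate_law, vmax=float(test_vmax), km=dict(test.rate_law.km))
        out = out.with_params({test.id: law})
    return out
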