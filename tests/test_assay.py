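"""Assay scheme assembly, simulation, conservation and coupling checks."""

import numpy as np
import pytest

from phkin.assay import (build_ode_system, check_coupling_excess,
                         conservation_residual, initial_state,
                         monitored_trace, simulate_assay)
from phkin.ratelaw import ConfigurationError, RateLaw
from phkin.schemes import ENZYMES, at_condition, load_scheme
from phkin.validation import (derivatives_by_name, max_relative_deviation,
                              simulate_fixed_step)

GRID_10MIN = np.arange(0.0, 10.0 + 1e-9, 1.0 / 6.0)


class TestBuildOdeSystem:
    def test_eno_is_a_two_species_system_with_opposed_derivatives(self, schemes):
        f, names = build_ode_system(schemes["ENO"])
        assert set(names) == {"P2G", "PEP"}
        y0, _ = initial_state(schemes["ENO"])
        dy = f(y0, 0.0)
        i_s, i_p = names.index("P2G"), names.index("PEP")
        assert dy[i_s] < 0 and dy[i_p] > 0
        assert dy[i_s] == pytest.approx(-dy[i_p], rel=1e-12)

    def test_ald_species_set_and_nadh_consumer(self, schemes):
        scheme = schemes["ALD"]
        _, names = build_ode_system(scheme)
        assert set(names) == {"F16BP", "DHAP", "GAP", "G3P", "NADH", "NAD"}
        consumers = [r.id for r in scheme.reactions
                     if r.stoichiometry.get("NADH", 0) < 0]
        assert consumers == ["g3pdh"]

    def test_all_vmax_zero_gives_zero_derivatives(self, schemes):
        scheme = schemes["PGI"]
        params = {}
        for rxn in scheme.reactions:
            law = rxn.rate_law
            params[rxn.id] = RateLaw(law.form, 0.0, dict(law.km), law.keq,
                                     law.vmax_units)
        f, names = build_ode_system(scheme, params)
        y0, _ = initial_state(scheme)
        assert np.allclose(f(y0, 0.0), 0.0)

    def test_rate_law_species_outside_state_is_config_error(self, schemes):
        import dataclasses
        scheme = schemes["ENO"]
        test = scheme.test_reaction
        bad_law = RateLaw(test.rate_law.form, 1.0,
                          dict(test.rate_law.km) | {"GHOST": 1.0},
                          test.rate_law.keq, test.rate_law.vmax_units)
        bad = dataclasses.replace(test, rate_law=bad_law,
                                  stoichiometry=dict(test.stoichiometry))
        broken = dataclasses.replace(scheme, reactions=[bad])
        with pytest.raises(ConfigurationError, match="GHOST"):
            build_ode_system(broken)

    def test_compiled_rhs_matches_naive_name_keyed_assembly(self, schemes):
        rng = np.random.default_rng(0)
        for scheme in schemes.values():
            f, names = build_ode_system(scheme)
            y0, _ = initial_state(scheme)
            y = y0 + rng.uniform(0.0, 0.2, len(y0))
            dy = f(y, 0.0)
            ref = derivatives_by_name(scheme, dict(zip(names, y)))
            for i, name in enumerate(names):
                assert dy[i] == pytest.approx(ref[name], rel=1e-12, abs=1e-12)


class TestSimulateAssay:
    def test_eno_mass_conservation(self, schemes):
        traj = simulate_assay(schemes["ENO"], times_min=GRID_10MIN)
        total = traj.concentrations["P2G"] + traj.concentrations["PEP"]
        assert np.max(np.abs(total - 6.0)) < 6.0 * 1e-6

    def test_no_start_substrate_means_constant_trajectory(self, schemes):
        import dataclasses
        scheme = dataclasses.replace(
            schemes["ENO"], initial_concentrations={"P2G": 0.0})
        traj = simulate_assay(scheme, times_min=GRID_10MIN)
        for series in traj.concentrations.values():
            assert np.allclose(series, series[0], atol=1e-12)

    @pytest.mark.parametrize("enzyme", ENZYMES)
    def test_conservation_laws_hold_for_every_scheme(self, schemes, enzyme):
        traj = simulate_assay(schemes[enzyme], times_min=GRID_10MIN)
        assert conservation_residual(traj, schemes[enzyme]) < 1e-6

    @pytest.mark.parametrize("enzyme", ENZYMES)
    def test_monitored_species_is_monotone_in_the_assay_direction(
            self, schemes, enzyme):
        scheme = schemes[enzyme]
        traj = simulate_assay(scheme, times_min=GRID_10MIN)
        diffs = np.diff(monitored_trace(traj, scheme))
        if scheme.direction == "increase":
            assert np.all(diffs >= -1e-9)
        else:
            assert np.all(diffs <= 1e-9)

    def test_time_grid_must_start_at_zero_and_increase(self, schemes):
        with pytest.raises(ValueError):
            simulate_assay(schemes["ENO"], times_min=[1.0, 2.0])
        with pytest.raises(ValueError):
            simulate_assay(schemes["ENO"], times_min=[0.0, 2.0, 1.0])

    def test_closed_uni_uni_relaxes_to_thermodynamic_equilibrium(self, schemes):
        # long-horizon ENO: P/S settles at Keq
        scheme = schemes["ENO"]
        keq = scheme.test_reaction.rate_law.keq
        traj = simulate_assay(scheme, times_min=np.linspace(0, 2000, 21))
        ratio = traj.concentrations["PEP"][-1] / traj.concentrations["P2G"][-1]
        assert ratio == pytest.approx(keq, rel=1e-4)


class TestFixedStepOracle:
    def test_uni_uni_matches_adaptive_solver_closely(self, schemes):
        grid = np.arange(0.0, 1.0 + 1e-9, 1.0 / 6.0)
        a = simulate_assay(schemes["ENO"], times_min=grid)
        b = simulate_fixed_step(schemes["ENO"], grid, dt=1e-3)
        assert max_relative_deviation(a, b) < 1e-5


class TestCouplingExcess:
    def test_default_surplus_keeps_ald_score_high(self, schemes):
        assert check_coupling_excess(schemes["ALD"]) >= 0.99

    def test_zero_coupling_vmax_scores_zero(self, schemes):
        scheme = schemes["ALD"]
        params = {}
        for rxn in scheme.reactions:
            if rxn.role == "coupling":
                law = rxn.rate_law
                params[rxn.id] = RateLaw(law.form, 0.0, dict(law.km), law.keq,
                                         law.vmax_units)
        assert check_coupling_excess(scheme, params) == pytest.approx(0.0, abs=1e-6)

    def test_direct_assay_scores_one_by_construction(self, schemes):
        assert check_coupling_excess(schemes["ENO"]) == pytest.approx(1.0, abs=1e-9)

    def test_doubling_test_vmax_doubles_initial_monitored_rate(self, schemes):
        # linearity of the observed rate in the test capacity when the
        # coupling cascade is in excess
        scheme = schemes["ALD"]
        grid = np.linspace(0.0, 0.5, 31)

        def initial_rate(factor):
            inst = at_condition(scheme, test_vmax=factor *
                                scheme.test_reaction.rate_law.vmax)
            traj = simulate_assay(inst, times_min=grid)
            mon = monitored_trace(traj, inst)
            return (mon[6] - mon[-1]) / (grid[-1] - grid[6])

        assert initial_rate(2.0) == pytest.approx(2 * initial_rate(1.0), rel=0.01)


class TestGapdhReverseVariants:
    def test_explicit_pgk_variant_maintains_a_small_bpg_pool(self):
        from phkin.schemes import gapdhr_explicit_pgk
        scheme = gapdhr_explicit_pgk()
        traj = simulate_assay(scheme)
        mon = monitored_trace(traj, scheme)
        assert np.all(np.diff(mon) <= 1e-9)  # NADH decays
        assert conservation_residual(traj, scheme) < 1e-6
        # 1,3BPG sits at its kinase-equilibrium level, far below the
        # lumped model's substrate pool
        assert 0 < traj.concentrations["BPG"].max() < 0.2


class TestDilutionScaling:
    def test_dilution_scales_extract_protein_not_coupling(self, schemes):
        base = load_scheme("ALD")
        diluted = at_condition(base, dilution_factor=4)
        assert diluted.protein == pytest.approx(base.protein / 4)
        test = diluted.test_reaction
        assert diluted.effective_vmax(test) == pytest.approx(
            base.effective_vmax(base.test_reaction) / 4)
        for rxn in diluted.reactions:
            if rxn.role == "coupling":
                assert diluted.effective_vmax(rxn) == pytest.approx(
                    base.effective_vmax(rxn))
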