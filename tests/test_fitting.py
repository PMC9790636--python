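"""Progression-curve fitting: cost, recovery, regularization, comparisons."""

from dataclasses import replace

import numpy as np
import pytest

from phkin.fitting import (ProgressionFitModel, compare_keq_modes,
                           compare_ph_dependence, informative_substrate)
from phkin.keq import KeqTable
from phkin.schemes import load_scheme
from phkin.synth import StudyDesign, generate_progression_curves


@pytest.fixture(scope="module")
def eno_problem():
    """Noise-free ENO curves over 4 pH values with a depleting substrate.

    A reduced 2PG load plus a large Keq drives the curves through the
    sub-Km regime, making both Vmax and Km identifiable.
    """
    scheme = replace(load_scheme("ENO"), initial_concentrations={"P2G": 0.8})
    tables = {"ENO": KeqTable("ENO", [6.0, 8.0], [500.0, 500.0])}
    phs = (6.4, 6.8, 7.2, 7.6)
    design = StudyDesign(ph_grid=phs, dilution_factors=(1,), replicates=1,
                         sigma_au=0.0)
    truth = {ph: 2.0 * np.exp(-0.5 * ((ph - 7.4) / 0.5) ** 2) for ph in phs}
    curves = generate_progression_curves(scheme, truth, design, seed=0,
                                         keq_tables=tables)
    return scheme, tables, truth, curves


class TestCost:
    def test_zero_at_ground_truth_on_noise_free_data(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        assert model.cost_from_values(truth) < 1e-8

    def test_penalty_vanishes_at_reference_km(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables, lam=7.0)
        theta = model.pack(truth, {"P2G": model.km_reference["P2G"]})
        r = model.residuals(theta)
        n_data = sum(len(c.times) for c in curves)
        assert np.sum(r[n_data:] ** 2) == pytest.approx(0.0, abs=1e-20)

    def test_perturbing_one_vmax_strictly_increases_cost(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        base = model.cost_from_values(truth)
        for factor in (1.05, 1.2):
            bumped = dict(truth)
            bumped[6.8] = truth[6.8] * factor
            assert model.cost_from_values(bumped) > base

    def test_invariant_to_curve_ordering(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model_a = ProgressionFitModel(scheme, curves, keq_tables=tables)
        model_b = ProgressionFitModel(scheme, list(reversed(curves)),
                                      keq_tables=tables)
        assert model_a.cost_from_values(truth) == pytest.approx(
            model_b.cost_from_values(truth), rel=1e-12)


class TestFit:
    def test_noise_free_recovery_from_perturbed_start(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        theta0 = model.pack(
            {ph: v * 2 for ph, v in truth.items()},
            {"P2G": model.km_reference["P2G"] * 2},
        )
        res = model.fit(theta0=theta0)
        for ph, v in truth.items():
            assert res.vmax[ph] == pytest.approx(v, rel=1e-3)
        assert res.km["P2G"] == pytest.approx(0.04, rel=0.01)
        assert res.converged

    def test_refit_from_optimum_is_stable(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        res = model.fit()
        res2 = model.fit(theta0=res.theta)
        assert res2.cost <= res.cost * (1 + 1e-8) + 1e-15

    def test_huge_lambda_pins_km_to_reference(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables, lam=1e9)
        res = model.fit()
        assert res.km["P2G"] == pytest.approx(model.km_reference["P2G"],
                                              rel=1e-4)

    def test_summary_mentions_estimates(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        res = ProgressionFitModel(scheme, curves, keq_tables=tables).fit()
        text = res.summary()
        assert "ENO" in text and "Km" in text and "SSE" in text

    def test_informative_substrate_choices(self):
        # the fitted Km belongs to the least-saturated substrate
        assert informative_substrate(load_scheme("ENO")) == "P2G"
        assert informative_substrate(load_scheme("HXK")) == "ATP"
        assert informative_substrate(load_scheme("GAPDHR")) == "NADH"


class TestPredict:
    def test_prediction_overlays_noise_free_training_data(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        res = model.fit()
        c = curves[1]
        traj = res.predict(c.ph, times_min=c.times)
        from phkin.calibration import PEP_CALIBRATION, abs_to_conc
        measured = abs_to_conc(c.absorbance, PEP_CALIBRATION) / 0.3
        assert np.max(np.abs(traj.concentrations["PEP"] - measured)) < 1e-4

    def test_rate_curve_at_t0_matches_pointwise_rate(self, eno_problem):
        from phkin.ratelaw import rate
        scheme, tables, truth, curves = eno_problem
        model = ProgressionFitModel(scheme, curves, keq_tables=tables)
        res = model.fit()
        ph = curves[0].ph
        traj = res.predict(ph, times_min=np.linspace(0, 1, 7))
        inst = model._apply(model._instance(ph, 1.0), res.vmax[ph], res.km)
        test = inst.test_reaction
        v0 = rate(test, {"P2G": 0.8, "PEP": 0.0},
                  vmax_mm_per_min=inst.effective_vmax(test))
        assert traj.fluxes[test.id][0] == pytest.approx(v0, rel=1e-9)

    def test_no_extrapolation_outside_fitted_ph_set(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        res = ProgressionFitModel(scheme, curves, keq_tables=tables).fit()
        with pytest.raises(ValueError, match="not in fitted set"):
            res.predict(5.5)


class TestKeqModes:
    def test_constant_keq_table_makes_modes_coincide(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        out = compare_keq_modes(scheme, curves, keq_tables=tables)
        assert out["max_relative_difference"] < 1e-6

    def test_near_equilibrium_sensitivity_grows_as_substrate_shrinks(self):
        # an assay pushed toward equilibrium feels the Keq mode; the
        # deviation grows monotonically as the start substrate shrinks
        base = load_scheme("ENO")
        tables = {"ENO": KeqTable("ENO", [6.0, 8.0], [0.5, 5.0])}
        phs = (6.4, 7.6)
        deviations = []
        for s0 in (6.0, 1.5, 0.4):
            scheme = replace(base, initial_concentrations={"P2G": s0})
            design = StudyDesign(ph_grid=phs, dilution_factors=(1,),
                                 replicates=1, sigma_au=0.0)
            truth = {ph: 2.0 for ph in phs}
            curves = generate_progression_curves(scheme, truth, design, seed=0,
                                                 keq_tables=tables)
            out = compare_keq_modes(scheme, curves, keq_tables=tables)
            deviations.append(out["max_relative_difference"])
        assert deviations[0] < deviations[1] < deviations[2]


class TestPhDependence:
    def test_vmax_varying_data_prefers_vmax_layout(self, eno_problem):
        scheme, tables, truth, curves = eno_problem
        out = compare_ph_dependence(scheme, curves, keq_tables=tables)
        assert out["winner"] == "vmax_varying"
        assert out["sse_vmax_varying"] < out["sse_km_varying"]
        assert out["n_params_vmax_varying"] == out["n_params_km_varying"]

    def test_km_varying_data_prefers_km_layout(self):
        scheme = replace(load_scheme("ENO"),
                         initial_concentrations={"P2G": 0.8})
        tables = {"ENO": KeqTable("ENO", [6.0, 8.0], [500.0, 500.0])}
        phs = (6.4, 6.8, 7.2, 7.6)
        design = StudyDesign(ph_grid=phs, dilution_factors=(1,), replicates=1,
                             sigma_au=0.0)
        vmax = {ph: 1.5 for ph in phs}
        km = {ph: {"P2G": 0.04 * 3 ** ((ph - 6.4) / 1.2)} for ph in phs}
        curves = generate_progression_curves(scheme, vmax, design, seed=0,
                                             keq_tables=tables, km_by_ph=km)
        out = compare_ph_dependence(scheme, curves, keq_tables=tables)
        assert out["winner"] == "km_varying"

    def test_single_ph_data_makes_layouts_equivalent(self):
        scheme = replace(load_scheme("ENO"),
                         initial_concentrations={"P2G": 0.8})
        tables = {"ENO": KeqTable("ENO", [6.0, 8.0], [500.0, 500.0])}
        design = StudyDesign(ph_grid=(6.8,), dilution_factors=(1,),
                             replicates=1, sigma_au=0.0)
        curves = generate_progression_curves(scheme, {6.8: 1.5}, design,
                                             seed=0, keq_tables=tables)
        out = compare_ph_dependence(scheme, curves, keq_tables=tables)
        denom = max(out["sse_vmax_varying"], out["sse_km_varying"], 1e-30)
        rel = abs(out["sse_vmax_varying"] - out["sse_km_varying"]) / denom
        assert rel < 1e-6 or denom < 1e-12
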