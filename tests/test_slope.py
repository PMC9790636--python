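"""Slope-based capacity estimation: windows, conversion, dilution selection."""

import numpy as np
import pytest

from phkin.calibration import NADH_CALIBRATION
from phkin.slope import (EstimationError, ProgressionCurve, background_rate,
                         estimate_vmax_slope, find_linear_window,
                         select_dilution_factors, slope_to_capacity)
from phkin.synth import StudyDesign, generate_progression_curves
from phkin.schemes import load_scheme


def make_curve(times, absorbance, background=None, **kwargs):
    defaults = dict(enzyme_id="ENO", ph=6.8, dilution_factor=1, replicate=1,
                    direction="increase", wavelength=240)
    defaults.update(kwargs)
    return ProgressionCurve(times=np.asarray(times),
                            absorbance=np.asarray(absorbance),
                            background=background, **defaults)


class TestBackgroundRate:
    def test_flat_background_is_zero(self):
        t = np.linspace(0, 5, 31)
        curve = make_curve(t, t * 0.01, background=(t, np.full_like(t, 0.5)))
        assert background_rate(curve) == pytest.approx(0.0, abs=1e-12)

    def test_linear_drift_recovered(self):
        t = np.linspace(0, 5, 31)
        curve = make_curve(t, t * 0.01, background=(t, 0.5 - 0.001 * t))
        assert background_rate(curve) == pytest.approx(-0.001, rel=1e-9)

    def test_missing_background_warns_and_returns_zero(self):
        t = np.linspace(0, 5, 31)
        curve = make_curve(t, t * 0.01)
        with pytest.warns(UserWarning, match="no background"):
            assert background_rate(curve) == 0.0

    def test_too_few_background_points_is_an_error(self):
        t = np.linspace(0, 5, 31)
        curve = make_curve(t, t * 0.01,
                           background=(np.array([0.0, 1.0]), np.array([0.5, 0.5])))
        with pytest.raises(EstimationError):
            background_rate(curve)


class TestFindLinearWindow:
    def test_exact_line_uses_all_points(self):
        t = np.linspace(0, 10, 60)
        (start, end), slope, r2 = find_linear_window(make_curve(t, 0.3 + 0.02 * t))
        assert (start, end) == (0, 59)
        assert slope == pytest.approx(0.02, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_line_then_plateau_stops_near_the_break(self):
        t = np.linspace(0, 10, 61)
        y = np.where(t <= 5.0, 0.02 * t, 0.1)  # break at index 30
        (_, end), slope, _ = find_linear_window(make_curve(t, y))
        # the R^2 rule covers the whole linear stretch and admits at most
        # a few plateau samples before the regression degrades
        assert 30 <= end <= 33
        assert slope == pytest.approx(0.02, rel=0.05)

    def test_pure_noise_fails_estimation(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 10, 61)
        y = 0.5 + rng.normal(0, 0.01, len(t))
        with pytest.raises(EstimationError, match="R\\^2"):
            find_linear_window(make_curve(t, y))

    def test_lag_skip_shifts_the_anchor(self):
        t = np.linspace(0, 10, 61)
        y = 0.3 + 0.02 * t
        (start, _), _, _ = find_linear_window(make_curve(t, y), lag_skip=3)
        assert start == 3


class TestSlopeToCapacity:
    def test_zero_slope_zero_capacity(self):
        assert slope_to_capacity(0.0, NADH_CALIBRATION, 6.0, 1) == 0.0

    def test_linearity_in_sample_dilution(self):
        c1 = slope_to_capacity(-0.01, NADH_CALIBRATION, 6.0, 1)
        c2 = slope_to_capacity(-0.01, NADH_CALIBRATION, 6.0, 2)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_monitored_amount_rate_before_scaling(self):
        # |-0.01| AU/min over the NAD(P)H line = 0.01/4.8365 umol/min
        cap = slope_to_capacity(-0.01, NADH_CALIBRATION, protein=1.0,
                                df_sample=1, df_assay=1, stoich=1,
                                assay_volume_ml=1.0)
        assert cap == pytest.approx(2.0676e-3, rel=1e-4)

    def test_stoichiometry_divides(self):
        c1 = slope_to_capacity(-0.01, NADH_CALIBRATION, 6.0, 1, stoich=1)
        c2 = slope_to_capacity(-0.01, NADH_CALIBRATION, 6.0, 1, stoich=2)
        assert c1 == pytest.approx(2 * c2, rel=1e-12)

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            slope_to_capacity(-0.01, NADH_CALIBRATION, 0.0, 1)


class TestSelectDilutionFactors:
    def test_outlier_dilution_discarded(self):
        kept = select_dilution_factors({1: 10.0, 2: 9.8, 4: 10.2, 32: 6.0})
        assert sorted(kept) == [1, 2, 4]

    def test_all_consistent_all_kept(self):
        kept = select_dilution_factors({1: 10.0, 2: 10.0, 4: 10.0, 8: 10.0})
        assert sorted(kept) == [1, 2, 4, 8]

    def test_two_inconsistent_dilutions_error(self):
        with pytest.raises(EstimationError, match="no two dilution"):
            select_dilution_factors({1: 10.0, 32: 3.0}, enzyme_id="TPI")

    def test_single_dilution_insufficient(self):
        with pytest.raises(EstimationError, match=">= 2"):
            select_dilution_factors({1: 10.0})

    def test_result_independent_of_insertion_order(self):
        a = {1: 10.0, 2: 9.8, 4: 10.2, 32: 6.0}
        b = dict(reversed(list(a.items())))
        assert sorted(select_dilution_factors(a)) == sorted(
            select_dilution_factors(b))


class TestEstimatePipeline:
    def test_noise_free_curves_recover_truth_within_two_percent(self):
        scheme = load_scheme("ENO")
        design = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2),
                             replicates=1, sigma_au=0.0, reaction_minutes=3.0)
        curves = generate_progression_curves(scheme, {6.8: 2.0}, design, seed=0)
        est = estimate_vmax_slope(curves, protein=6.0, stoich=1)[0]
        assert est.value == pytest.approx(2.0, rel=0.02)

    def test_flat_curves_give_zero_capacity(self):
        t = np.linspace(0, 10, 61)
        curves = [make_curve(t, np.full_like(t, 0.3), dilution_factor=df,
                             background=(t[:31], np.full(31, 0.3)))
                  for df in (1, 2)]
        est = estimate_vmax_slope(curves, protein=6.0)[0]
        assert est.value == pytest.approx(0.0, abs=1e-10)

    def test_noisy_monte_carlo_recovery_within_five_percent(self):
        # repeated noisy realizations stay within 5% of truth on average
        scheme = load_scheme("ENO")
        design = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2),
                             replicates=3, sigma_au=0.002)
        errors = []
        for seed in range(40):
            curves = generate_progression_curves(scheme, {6.8: 2.0}, design,
                                                 seed=seed)
            est = estimate_vmax_slope(curves, protein=6.0, stoich=1)[0]
            errors.append(abs(est.value - 2.0) / 2.0)
        assert np.median(errors) < 0.05

    def test_dilution_invariance_of_estimates(self):
        # the same ground truth observed at different dilutions gives
        # consistent capacity estimates
        scheme = load_scheme("ENO")
        design = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2, 4),
                             replicates=1, sigma_au=0.0)
        curves = generate_progression_curves(scheme, {6.8: 2.0}, design, seed=0)
        est = estimate_vmax_slope(curves, protein=6.0, stoich=1)[0]
        assert sorted(est.dilution_factors_used) == [1, 2, 4]
        assert est.spread / est.value < 0.02

    def test_scale_equivariance(self):
        scheme = load_scheme("ENO")
        design = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2),
                             replicates=1, sigma_au=0.0, reaction_minutes=3.0)
        values = []
        for scale in (1.0, 1.7):
            curves = generate_progression_curves(scheme, {6.8: 2.0 * scale},
                                                 design, seed=0)
            values.append(estimate_vmax_slope(curves, protein=6.0,
                                              stoich=1)[0].value)
        assert values[1] / values[0] == pytest.approx(1.7, rel=0.02)

    def test_shared_drift_cancels_via_background_correction(self):
        scheme = load_scheme("ENO")
        base = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2),
                           replicates=1, sigma_au=0.0)
        drifted = StudyDesign(ph_grid=(6.8,), dilution_factors=(1, 2),
                              replicates=1, sigma_au=0.0,
                              drift_au_per_min=0.003)
        v0 = estimate_vmax_slope(
            generate_progression_curves(scheme, {6.8: 2.0}, base, seed=0),
            protein=6.0, stoich=1)[0].value
        v1 = estimate_vmax_slope(
            generate_progression_curves(scheme, {6.8: 2.0}, drifted, seed=0),
            protein=6.0, stoich=1)[0].value
        assert v1 == pytest.approx(v0, rel=0.01)
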