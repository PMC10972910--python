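"""Calibration fitting, SSE matrix-effect computation and quantification."""

import numpy as np
import pytest

from mycomet.quant import (
    CalibrationFit,
    CalibrationLevel,
    MatrixEffect,
    back_calculate,
    compute_sse,
    fit_calibration,
    matrix_correct,
    quantify_sample,
    replicate_sse,
    replicate_summary,
    to_ug_per_kg,
)
from mycomet.simulate import CalibrationSimSpec, simulate_calibration_pair
from oracles import least_squares_oracle

SOLVENT_LEVELS = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0)
SPIKED_LEVELS = (125.0, 250.0, 500.0, 1000.0, 2000.0)


def levels(xs, ys):
    return [CalibrationLevel(x, y) for x, y in zip(xs, ys)]


class TestFitCalibration:
    def test_noiseless_line_recovered_exactly(self):
        fit = fit_calibration(levels(SOLVENT_LEVELS, [2 * c + 5 for c in SOLVENT_LEVELS]))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-9)
        assert fit.correlation_r == pytest.approx(1.0, abs=1e-12)

    def test_two_point_line(self):
        fit = fit_calibration(levels([1.0, 2.0], [1.0, 3.0]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = list(SOLVENT_LEVELS)
        y = [1.7 * c + 40 + rng.normal(0, 5) for c in x]
        fit = fit_calibration(levels(x, y))
        slope, intercept = least_squares_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert abs(fit.correlation_r) <= 1.0

    def test_one_over_x_weighting_exact_on_noiseless_line(self):
        lv = levels(SOLVENT_LEVELS, [2 * c + 5 for c in SOLVENT_LEVELS])
        fit = fit_calibration(lv, weighting="1/x")
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(5.0, abs=1e-7)
        with pytest.raises(ValueError):
            fit_calibration(lv, weighting="1/x2")

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(levels([5.0], [10.0]))
        with pytest.raises(ValueError):
            fit_calibration(levels([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]))


class TestSse:
    def test_equal_slopes_give_100(self):
        fit = CalibrationFit(1.5, 0.0, 1.0, 6)
        assert compute_sse(fit, fit).sse_percent == pytest.approx(100.0)

    def test_half_slope_gives_50(self):
        solvent = CalibrationFit(2.0, 0.0, 1.0, 6)
        spiked = CalibrationFit(1.0, 0.0, 1.0, 6)
        assert compute_sse(spiked, solvent).sse_percent == pytest.approx(50.0)

    def test_zero_solvent_slope_rejected(self):
        with pytest.raises(ValueError):
            compute_sse(CalibrationFit(1.0, 0, 1, 6), CalibrationFit(0.0, 0, 1, 6))

    def test_scale_invariance(self):
        x = list(SPIKED_LEVELS)
        spiked = levels(x, [0.552 * c for c in x])
        solvent = levels(x, [1.0 * c for c in x])
        base = compute_sse(fit_calibration(spiked), fit_calibration(solvent))
        for c in (0.1, 3.0, 100.0):
            scaled = compute_sse(
                fit_calibration(levels(x, [0.552 * v * c for v in x])),
                fit_calibration(levels(x, [v * c for v in x])),
            )
            assert scaled.sse_percent == pytest.approx(base.sse_percent, abs=1e-9)

    def test_scaled_solvent_curve_gives_100k(self):
        x = list(SOLVENT_LEVELS)
        solvent = fit_calibration(levels(x, [3.0 * c + 7 for c in x]))
        for k in (0.25, 0.552, 1.3):
            spiked = fit_calibration(levels(x, [k * (3.0 * c + 7) for c in x]))
            # slope scales by k; SSE = 100 k
            assert compute_sse(spiked, solvent).sse_percent == pytest.approx(
                100 * k, abs=1e-9
            )

    def test_replicate_sse_spread(self):
        solvent = CalibrationFit(1.0, 0.0, 1.0, 6)
        reps = [
            levels(SPIKED_LEVELS, [s * c for c in SPIKED_LEVELS])
            for s in (0.54, 0.552, 0.56)
        ]
        me = replicate_sse(reps, solvent)
        assert me.sse_percent == pytest.approx(100 * (0.54 + 0.552 + 0.56) / 3)
        assert me.sse_sd == pytest.approx(float(np.std([54.0, 55.2, 56.0], ddof=1)))

    def test_noiseless_simulated_pair_returns_exact_sse(self):
        spec = CalibrationSimSpec(noise_cv=0.0, suppression_factor=0.552)
        solvent, spiked = simulate_calibration_pair(spec, seed=0)
        me = replicate_sse(spiked, fit_calibration(solvent))
        assert me.sse_percent == pytest.approx(55.2, abs=1e-9)
        assert me.sse_sd == pytest.approx(0.0, abs=1e-9)

    def test_sse_estimator_unbiased_under_noise(self):
        """With 2% response noise and triplicate curves at the spiked levels,
        the mean SSE over 200 seeded repetitions stays within Monte-Carlo
        error of 100 x suppression."""
        spec = CalibrationSimSpec(noise_cv=0.02, suppression_factor=0.552)
        estimates = []
        for seed in range(200):
            solvent, spiked = simulate_calibration_pair(spec, seed=seed)
            estimates.append(
                replicate_sse(spiked, fit_calibration(solvent)).sse_percent
            )
        mean = float(np.mean(estimates))
        sem = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))
        assert abs(mean - 55.2) < 4 * sem + 0.1


class TestBackCalculateAndCorrection:
    FIT = CalibrationFit(2.0, 5.0, 0.999, 6)

    def test_intercept_maps_to_zero(self):
        assert back_calculate(5.0, self.FIT) == pytest.approx(0.0)

    def test_known_concentration_recovered(self):
        assert back_calculate(2.0 * 250 + 5.0, self.FIT) == pytest.approx(250.0)

    def test_roundtrip_on_noiseless_line(self):
        lv = levels(SOLVENT_LEVELS, [3.3 * c + 12 for c in SOLVENT_LEVELS])
        fit = fit_calibration(lv)
        for point in lv:
            assert back_calculate(point.response, fit) == pytest.approx(
                point.nominal_concentration, abs=1e-8
            )

    def test_matrix_correct(self):
        assert matrix_correct(100.0, MatrixEffect(100.0)) == pytest.approx(100.0)
        assert matrix_correct(100.0, MatrixEffect(50.0)) == pytest.approx(200.0)

    def test_nonpositive_sse_rejected(self):
        with pytest.raises(ValueError):
            MatrixEffect(0.0)

    def test_quantification_roundtrip_recovers_truth(self):
        """Simulate suppressed responses at a known concentration, quantify
        on the solvent curve, correct with the measured SSE: the truth is
        recovered within noise-determined bounds."""
        true_conc = 400.0
        spec = CalibrationSimSpec(noise_cv=0.02, suppression_factor=0.552)
        rng = np.random.default_rng(5)
        recovered = []
        for seed in range(50):
            solvent, spiked = simulate_calibration_pair(spec, seed=seed)
            solvent_fit = fit_calibration(solvent)
            me = replicate_sse(spiked, solvent_fit)
            response = 0.552 * spec.solvent_slope * true_conc * (
                1 + rng.normal(0, spec.noise_cv)
            )
            conc = matrix_correct(back_calculate(response, solvent_fit), me)
            recovered.append(conc)
        assert np.mean(recovered) == pytest.approx(true_conc, rel=0.03)

    def test_below_intercept_flagged_not_negative(self):
        res = quantify_sample([1.0], self.FIT, MatrixEffect(55.2), 0.5, 0.5)[0]
        assert res.below_loq
        assert res.extract_concentration == 0.0
        assert res.per_sample_concentration == 0.0


class TestUnits:
    def test_unit_arithmetic(self):
        assert to_ug_per_kg(100.0, 0.5, 0.5) == pytest.approx(100.0)
        assert to_ug_per_kg(0.0, 0.5, 0.5) == 0.0

    def test_doubling_mass_halves_result(self):
        assert to_ug_per_kg(100.0, 0.5, 1.0) == pytest.approx(
            to_ug_per_kg(100.0, 0.5, 0.5) / 2
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            to_ug_per_kg(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            to_ug_per_kg(1.0, 1.0, -2.0)


class TestReplicateSummary:
    def test_constant_values(self):
        assert replicate_summary([5.0, 5.0, 5.0]) == (5.0, 0.0)

    def test_two_values(self):
        mean, sd = replicate_summary([1.0, 3.0])
        assert mean == 2.0
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        vals = list(rng.uniform(100, 900, size=12))
        mean, sd = replicate_summary(vals)
        m = sum(vals) / len(vals)
        s = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert mean == pytest.approx(m, abs=1e-10)
        assert sd == pytest.approx(s, abs=1e-10)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary([1.0])
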