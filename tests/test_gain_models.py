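"""Tests for the candidate gain models, fitting, BIC and comparisons."""

import math

import numpy as np
import pytest

from swaybayes import (
    AttributionParams,
    GainCurve,
    FitResult,
    V_SAT,
    aggregate_slopes,
    bic_score,
    build_comparison,
    compare_models,
    fit_model,
    loglog_slope,
    model_constant,
    model_log_saturation,
    model_piecewise,
    predicted_gain,
    read_gain_curves,
    write_gain_curves,
)
from swaybayes.synthetic import generate_gain_curves

STUDY_V = np.array([1.2566, 3.7699, 31.416, 125.66, 188.50])


def power_law_curve(sigma_c2=0.34, alpha=1.32, subject_id="s00"):
    gains = predicted_gain(STUDY_V, AttributionParams(sigma_c2, alpha))
    return GainCurve(STUDY_V, gains, subject_id=subject_id)


class TestModelFunctions:
    def test_constant(self):
        assert model_constant(1.2, 0.8) == 0.8
        np.testing.assert_array_equal(model_constant(STUDY_V, 0.3), np.full(5, 0.3))

    def test_log_saturation_example(self):
        # m=1 at the saturation velocity: amplitude ln(3.8), gain ln(3.8)/2.8
        assert model_log_saturation(2.8, 1.0) * 2.8 == pytest.approx(math.log(3.8))
        assert model_log_saturation(2.8, 1.0) == pytest.approx(0.4768, abs=1e-4)

    def test_log_saturation_amplitude_saturates(self):
        amp_at = lambda s: model_log_saturation(s, 0.7) * s
        assert amp_at(V_SAT) == pytest.approx(amp_at(10 * V_SAT), rel=1e-12)

    def test_log_saturation_asymptotic_slope(self):
        # constant numerator: log-log gain slope tends to -1 at large s
        s = np.array([100.0, 1000.0])
        g = model_log_saturation(s, 1.3)
        assert loglog_slope(s, g) == pytest.approx(-1.0, abs=1e-12)

    def test_piecewise_decade_decay(self):
        assert model_piecewise(37.0, 1.0, 3.7, 1.0) == pytest.approx(0.1)

    def test_piecewise_continuity_and_nesting(self):
        g0, s_c = 0.8, 3.7
        assert model_piecewise(s_c, g0, s_c, 2.0) == g0
        assert model_piecewise(s_c * (1 + 1e-12), g0, s_c, 2.0) == pytest.approx(g0, rel=1e-9)
        np.testing.assert_allclose(
            model_piecewise(STUDY_V, 0.5, 10.0, 0.0), model_constant(STUDY_V, 0.5)
        )

    @pytest.mark.parametrize("func,args", [
        (model_log_saturation, (1.0,)),
        (model_piecewise, (0.5, 3.0, 1.0)),
    ])
    def test_nonpositive_velocity_rejected(self, func, args):
        with pytest.raises(ValueError):
            func(-1.0, *args)


class TestBic:
    def test_hand_evaluation(self):
        # n*ln(rss/n) + k*ln(n) with rss/n = e^-3
        assert bic_score(5, 5 * math.exp(-3), 2) == pytest.approx(
            -15.0 + 2 * math.log(5), abs=1e-9
        )

    def test_doubling_rss_adds_n_log2(self):
        assert bic_score(5, 2e-3, 1) - bic_score(5, 1e-3, 1) == pytest.approx(
            5 * math.log(2)
        )

    def test_parameter_penalty(self):
        assert bic_score(5, 1e-3, 3) - bic_score(5, 1e-3, 1) == pytest.approx(
            2 * math.log(5)
        )

    def test_known_variance_form(self):
        assert bic_score(5, 2e-3, 2, noise_variance=4e-4) == pytest.approx(
            5.0 + 2 * math.log(5)
        )

    def test_unidentifiable_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            bic_score(2, 1e-3, 3)


class TestFitModel:
    def test_attribution_noise_free_round_trip(self):
        fit = fit_model(power_law_curve(), "attribution")
        assert fit.params["sigma_c2"] == pytest.approx(0.34, abs=1e-4)
        assert fit.params["alpha"] == pytest.approx(1.32, abs=1e-4)
        assert fit.rss < 1e-10

    def test_constant_fit_is_mean(self):
        curve = GainCurve(STUDY_V, np.array([0.2, 0.4, 0.3, 0.5, 0.1]))
        fit = fit_model(curve, "constant")
        assert fit.params["g0"] == pytest.approx(0.3)
        # LS identity: rss = n * var
        assert fit.rss == pytest.approx(np.sum((curve.gains - 0.3) ** 2))

    def test_flat_gains_fit_exactly(self):
        curve = GainCurve(STUDY_V, np.ones(5) * 0.5)
        const = fit_model(curve, "constant")
        attr = fit_model(curve, "attribution")
        assert const.rss == 0.0
        # attribution recovers the alpha=2 branch with equivalent (zero) rss
        assert attr.params["alpha"] == pytest.approx(2.0, abs=1e-6)
        assert attr.rss < 1e-12

    def test_noise_free_round_trip_other_families(self):
        for model, params in [
            ("log_saturation", {"m": 0.9}),
            ("piecewise", {"g0": 0.7, "s_c": 10.0, "beta": 0.9}),
        ]:
            [curve] = generate_gain_curves(model, params, noise_sd=0.0, n_subjects=1)
            fit = fit_model(curve, model)
            assert fit.rss < 1e-12
            for key, val in params.items():
                assert fit.params[key] == pytest.approx(val, rel=1e-3)

    def test_monte_carlo_alpha_recovery(self):
        """200 noisy replicates (gain noise sd 0.02): median |alpha error| < 0.15."""
        rng = np.random.default_rng(0)
        truth = predicted_gain(STUDY_V, AttributionParams(0.34, 1.32))
        errs = []
        for _ in range(200):
            g = np.maximum(truth + rng.normal(0.0, 0.02, 5), 0.0)
            fit = fit_model(GainCurve(STUDY_V, g), "attribution")
            errs.append(abs(fit.params["alpha"] - 1.32))
        assert np.median(errs) < 0.15

    def test_richer_model_never_fits_worse_than_nested(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            g = np.maximum(0.3 + rng.normal(0, 0.05, 5), 0.0)
            curve = GainCurve(STUDY_V, g)
            rss_const = fit_model(curve, "constant").rss
            assert fit_model(curve, "piecewise").rss <= rss_const + 1e-10
            assert fit_model(curve, "attribution").rss <= rss_const + 1e-10

    def test_fit_is_deterministic(self):
        curve = generate_gain_curves(
            "attribution", {"sigma_c2": 0.34, "alpha": 1.32}, noise_sd=0.02, seed=5
        )[0]
        a = fit_model(curve, "piecewise")
        b = fit_model(curve, "piecewise")
        assert a.rss == b.rss and a.params == b.params

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(power_law_curve(), "kalman")


def _fake_fit(bic):
    return FitResult(model_name="m", params={}, rss=1.0, n=5, k=1, bic=bic)


class TestCompareModels:
    def test_zero_variance_reported_not_p_zero(self):
        fits_a = {f"s{i}": _fake_fit(-3.0) for i in range(5)}
        fits_b = {f"s{i}": _fake_fit(-5.0) for i in range(5)}
        result = compare_models(fits_a, fits_b)
        assert not result.valid
        assert math.isnan(result.p)

    def test_hand_computed_t(self):
        diffs = [-8.0, -9.0, -7.0, -8.5, -7.5]
        fits_a = {f"s{i}": _fake_fit(d) for i, d in enumerate(diffs)}
        fits_b = {f"s{i}": _fake_fit(0.0) for i in range(5)}
        result = compare_models(fits_a, fits_b)
        expected_t = np.mean(diffs) / (np.std(diffs, ddof=1) / math.sqrt(5))
        assert result.t == pytest.approx(expected_t)
        assert result.p < 0.001

    def test_swapping_models_negates_t(self):
        rng = np.random.default_rng(1)
        fits_a = {f"s{i}": _fake_fit(float(rng.normal(-5, 1))) for i in range(6)}
        fits_b = {f"s{i}": _fake_fit(float(rng.normal(-3, 1))) for i in range(6)}
        fwd = compare_models(fits_a, fits_b)
        rev = compare_models(fits_b, fits_a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"s0": _fake_fit(1.0)}, {"s0": _fake_fit(2.0)})


class TestModelSelection:
    def test_constant_truth_penalises_attribution(self):
        """On constant-gain truth the 1-parameter model wins the known-variance BIC."""
        for seed in range(3):
            curves = generate_gain_curves(
                "constant", {"g0": 0.5}, noise_sd=0.02, n_subjects=10, seed=seed
            )
            report = build_comparison(curves, noise_variance=0.02**2)
            assert report.mean_bic["constant"] <= report.mean_bic["attribution"]

    def test_attribution_truth_wins_known_variance_bic(self):
        curves = generate_gain_curves(
            "attribution", {"sigma_c2": 0.34, "alpha": 1.32},
            noise_sd=0.02, n_subjects=10, seed=0,
        )
        report = build_comparison(curves, noise_variance=0.02**2)
        assert min(report.mean_bic, key=report.mean_bic.get) == "attribution"
        assert report.paired_tests["constant"].p < 0.05


class TestSlopes:
    def test_exact_power_law(self):
        gains = 2.0 * STUDY_V ** (-0.7)
        assert loglog_slope(STUDY_V, gains) == pytest.approx(-0.7, abs=1e-12)

    def test_healthy_printed_parameters(self, study_velocities, healthy_attribution_params):
        slopes = [
            loglog_slope(study_velocities, predicted_gain(study_velocities, p))
            for p in healthy_attribution_params
        ]
        np.testing.assert_allclose(slopes, [-0.68, -0.72, -0.97], atol=1e-12)
        mean, sd = aggregate_slopes(slopes)
        assert mean == pytest.approx(-0.79, abs=1e-9)
        assert sd == pytest.approx(0.157, abs=5e-4)

    def test_patient_printed_parameters(self, study_velocities, patient_attribution_params):
        slopes = [
            loglog_slope(study_velocities, predicted_gain(study_velocities, p))
            for p in patient_attribution_params
        ]
        np.testing.assert_allclose(slopes, [-0.30, -0.15], atol=1e-12)
        mean, sd = aggregate_slopes(slopes)
        assert mean == pytest.approx(-0.225, abs=1e-9)
        assert sd == pytest.approx(0.106, abs=5e-4)

    def test_slope_equals_alpha_minus_two_for_any_grid(self):
        v = np.geomspace(0.5, 300.0, 11)
        for alpha in (1.03, 1.5, 2.0, 2.5):
            p = AttributionParams(sigma_c2=0.52, alpha=alpha)
            assert loglog_slope(v, predicted_gain(v, p)) == pytest.approx(
                alpha - 2.0, abs=1e-10
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            loglog_slope([1.0], [0.5])
        with pytest.raises(ValueError):
            loglog_slope([1.0, 2.0], [0.5, 0.0])
        with pytest.raises(ValueError):
            aggregate_slopes([-0.7])


class TestGainCurveIO:
    def test_round_trip(self, tmp_path):
        curves = generate_gain_curves(
            "attribution", {"sigma_c2": 0.34, "alpha": 1.32},
            noise_sd=0.02, n_subjects=3, seed=7,
        )
        path = tmp_path / "gains.csv"
        write_gain_curves(curves, path)
        back = read_gain_curves(path)
        assert [c.subject_id for c in back] == [c.subject_id for c in curves]
        for a, b in zip(curves, back):
            np.testing.assert_allclose(b.velocities, a.velocities, rtol=1e-11)
            np.testing.assert_allclose(b.gains, a.gains, rtol=1e-11)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,velocity_cm_s\ns0,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_gain_curves(path)

    @pytest.mark.parametrize(
        "velocities,gains",
        [
            ([1.0], [0.5]),
            ([2.0, 1.0], [0.5, 0.4]),
            ([1.0, 2.0], [0.5, -0.1]),
            ([-1.0, 2.0], [0.5, 0.4]),
        ],
    )
    def test_invalid_curves_rejected(self, velocities, gains):
        with pytest.raises(ValueError):
            GainCurve(np.array(velocities), np.array(gains))
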