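"""Tests for normative-template estimation and zero-free-parameter prediction."""

import numpy as np
import pytest
from scipy import stats as sps

from csfkit import (
    CSFParams,
    CSFTemplate,
    correlation_table,
    estimate_template,
    evaluate_csf,
    fit_cohort,
    generate_cohort,
    loo_evaluate,
    predict_subject_csf,
    zero_noise_config,
)
from csfkit.cohort import GeneratorConfig


@pytest.fixture(scope="module")
def exact_cohort():
    """Zero-noise cohort whose links hold exactly."""
    return generate_cohort(zero_noise_config(n=12), seed=17)


@pytest.fixture(scope="module")
def noisy_sine_cohort():
    cfg = GeneratorConfig(
        n=20, tests={"csf_sine": GeneratorConfig().tests["csf_sine"]}
    )
    return generate_cohort(cfg, seed=23)


class TestEstimateTemplate:
    def test_exact_linear_cohort_recovers_links(self, exact_cohort):
        cfg = exact_cohort.config
        template = estimate_template(exact_cohort, "csf_sine")
        assert template.m_cs == pytest.approx(cfg.m_cs, abs=1e-4)
        assert template.c_cs == pytest.approx(cfg.c_cs, abs=1e-4)
        assert template.m_sf == pytest.approx(cfg.m_sf, abs=1e-4)
        assert template.c_sf == pytest.approx(cfg.c_sf, abs=1e-4)

    def test_constant_bandwidth_gives_template_mean(self, exact_cohort):
        template = estimate_template(exact_cohort, "csf_sine")
        assert template.beta_t == pytest.approx(exact_cohort.config.beta_t, abs=1e-4)
        assert template.delta_t == pytest.approx(exact_cohort.config.delta_t, abs=1e-4)

    def test_links_match_normal_equations_oracle(self, noisy_sine_cohort):
        fits = fit_cohort(noisy_sine_cohort, "csf_sine", seed=0)
        template = estimate_template(noisy_sine_cohort, "csf_sine", fits=fits)
        letter = np.array([r.letter_cs for r in noisy_sine_cohort.subjects])
        peak = np.array([fits[r.id].params.peak_logcs for r in noisy_sine_cohort.subjects])
        X = np.column_stack([letter, np.ones_like(letter)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ peak)
        assert template.m_cs == pytest.approx(slope, abs=1e-10)
        assert template.c_cs == pytest.approx(intercept, abs=1e-10)

    def test_too_few_subjects_rejected(self):
        cohort = generate_cohort(zero_noise_config(n=2), seed=0)
        with pytest.raises(ValueError):
            estimate_template(cohort, "csf_sine")

    def test_zero_variance_predictor_named(self, exact_cohort):
        import dataclasses

        frozen = dataclasses.replace(exact_cohort)
        frozen.subjects = [
            dataclasses.replace(r, far_acuity=0.1) for r in exact_cohort.subjects
        ]
        with pytest.raises(ValueError, match="far acuity"):
            estimate_template(frozen, "csf_sine")

    def test_template_round_trips_through_file(self, tmp_path, exact_cohort):
        template = estimate_template(exact_cohort, "csf_sine")
        path = tmp_path / "template.txt"
        template.to_file(path)
        back = CSFTemplate.from_file(path)
        assert back.as_dict() == pytest.approx(template.as_dict())
        assert back.test_id == template.test_id


class TestPredictSubjectCsf:
    def test_centroid_property(self, noisy_sine_cohort):
        """Predicting at the cohort-mean inputs returns the mean fitted peaks."""
        fits = fit_cohort(noisy_sine_cohort, "csf_sine", seed=0)
        template = estimate_template(noisy_sine_cohort, "csf_sine", fits=fits)
        mean_letter = np.mean([r.letter_cs for r in noisy_sine_cohort.subjects])
        mean_acuity = np.mean([r.far_acuity for r in noisy_sine_cohort.subjects])
        pred = predict_subject_csf(template, mean_letter, mean_acuity)
        mean_peak = np.mean([f.params.peak_logcs for f in fits.values()])
        mean_lsf = np.mean([np.log10(f.params.peak_sf) for f in fits.values()])
        assert pred.peak_logcs == pytest.approx(mean_peak, abs=1e-10)
        assert np.log10(pred.peak_sf) == pytest.approx(mean_lsf, abs=1e-10)

    def test_letter_cs_shift_is_pure_vertical_shift(self):
        template = CSFTemplate("t", beta_t=3.0, delta_t=0.4, m_cs=0.8, c_cs=0.7,
                               m_sf=-1.0, c_sf=0.6)
        a = predict_subject_csf(template, 1.5, 0.0)
        b = predict_subject_csf(template, 1.8, 0.0)
        sfs = np.array([4.0, 8.0, 16.0])  # at/above both peaks
        diff = evaluate_csf(b, sfs) - evaluate_csf(a, sfs)
        np.testing.assert_allclose(diff, 0.8 * 0.3, atol=1e-12)

    def test_exact_cohort_prediction_matches_generative_curve(self, exact_cohort):
        template = estimate_template(exact_cohort, "csf_sine")
        rec = exact_cohort.subjects[0]
        pred = predict_subject_csf(template, rec.letter_cs, rec.far_acuity)
        sfs = np.array(exact_cohort.test_specs["csf_sine"].frequencies)
        np.testing.assert_allclose(
            evaluate_csf(pred, sfs), evaluate_csf(rec.true_params, sfs), atol=1e-3
        )

    def test_non_finite_inputs_rejected(self):
        template = CSFTemplate("t", 3.0, 0.4, 0.8, 0.7, -1.0, 0.6)
        with pytest.raises(ValueError):
            predict_subject_csf(template, float("nan"), 0.0)


class TestLooEvaluate:
    def test_zero_noise_predictions_are_exact(self, exact_cohort):
        ev = loo_evaluate(exact_cohort, "csf_sine", seed=0)
        assert np.all(ev.per_subject["rmse_predicted"] < 1e-3)

    def test_unity_line_property(self, noisy_sine_cohort):
        ev = loo_evaluate(noisy_sine_cohort, "csf_sine", seed=0)
        gap = ev.per_subject["rmse_predicted"] - ev.per_subject["rmse_fitted"]
        assert np.all(gap >= -1e-6)

    def test_folds_independent_of_subject_order(self, exact_cohort):
        import dataclasses

        shuffled = dataclasses.replace(
            exact_cohort, subjects=list(reversed(exact_cohort.subjects))
        )
        a = loo_evaluate(exact_cohort, "csf_sine", seed=0)
        b = loo_evaluate(shuffled, "csf_sine", seed=0)
        assert list(a.per_subject.index) == list(b.per_subject.index)
        np.testing.assert_allclose(
            a.per_subject["rmse_predicted"], b.per_subject["rmse_predicted"],
            atol=1e-12,
        )

    def test_requires_four_subjects(self):
        cohort = generate_cohort(zero_noise_config(n=3), seed=0)
        with pytest.raises(ValueError):
            loo_evaluate(cohort, "csf_sine")

    def test_summary_contains_paired_t(self, noisy_sine_cohort):
        ev = loo_evaluate(noisy_sine_cohort, "csf_sine", seed=0)
        assert "t_predicted_vs_test_retest" in ev.summary
        assert ev.summary["df"] == noisy_sine_cohort.n - 1


class TestCorrelationTable:
    def test_perfect_linear_relation_gives_r_one(self):
        """Force fitted peak logCS to track letter CS exactly via zero noise."""
        cohort = generate_cohort(zero_noise_config(n=10), seed=31)
        table = correlation_table(cohort, ["csf_sine"])
        row = table[
            (table.measure == "letter_cs") & (table.quantity == "peak_logcs")
        ].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-6)
        assert row.sig == "**"

    def test_matches_covariance_formula_oracle(self, noisy_sine_cohort):
        fits = fit_cohort(noisy_sine_cohort, "csf_sine", seed=0)
        table = correlation_table(
            noisy_sine_cohort, ["csf_sine"], fits_by_test={"csf_sine": fits}
        )
        letter = np.array([r.letter_cs for r in noisy_sine_cohort.subjects])
        peak = np.array(
            [fits[r.id].params.peak_logcs for r in noisy_sine_cohort.subjects]
        )
        r_oracle = float(
            np.sum((letter - letter.mean()) * (peak - peak.mean()))
            / np.sqrt(np.sum((letter - letter.mean()) ** 2)
                      * np.sum((peak - peak.mean()) ** 2))
        )
        row = table[
            (table.measure == "letter_cs") & (table.quantity == "peak_logcs")
        ].iloc[0]
        assert row.r == pytest.approx(r_oracle, abs=1e-12)

    def test_orthogonal_predictor_gives_zero_r(self, noisy_sine_cohort):
        fits = fit_cohort(noisy_sine_cohort, "csf_sine", seed=0)
        peak = np.array(
            [fits[r.id].params.peak_logcs for r in noisy_sine_cohort.subjects]
        )
        rng = np.random.default_rng(2)
        x = rng.normal(size=peak.size)
        resid = x - np.polyval(np.polyfit(peak, x, 1), peak)
        r, _ = sps.pearsonr(resid, peak)
        assert r == pytest.approx(0.0, abs=1e-10)
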