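"""Tests for the synthetic cohort generator and instrument emulation."""

import numpy as np
import pytest
from scipy import stats as sps

from csfkit import (
    CSFParams,
    GeneratorConfig,
    TestSpec,
    bland_altman,
    evaluate_csf,
    generate_cohort,
    quantize_chart,
    simulate_test_session,
    zero_noise_config,
)
from csfkit.cohort import ConfigError, default_test_specs


class TestGenerateCohort:
    def test_empty_cohort_valid(self):
        cohort = generate_cohort(GeneratorConfig(n=0), seed=0)
        assert cohort.n == 0 and set(cohort.test_specs) == set(default_test_specs())

    def test_zero_noise_links_hold_exactly(self):
        cfg = zero_noise_config(n=10)
        cohort = generate_cohort(cfg, seed=3)
        for rec in cohort.subjects:
            t = rec.true_params
            assert t.peak_logcs == pytest.approx(
                cfg.m_cs * rec.letter_cs + cfg.c_cs, abs=1e-12
            )
            assert np.log10(t.peak_sf) == pytest.approx(
                cfg.m_sf * rec.far_acuity + cfg.c_sf, abs=1e-12
            )
            assert t.bandwidth_oct == cfg.beta_t
            assert t.truncation == cfg.delta_t
            # emitted data sit exactly on the generative curve
            sfs = cohort.test_specs["csf_sine"].frequencies
            np.testing.assert_allclose(
                rec.csf_sessions["csf_sine"][0],
                np.atleast_1d(evaluate_csf(t, np.array(sfs))),
                atol=1e-12,
            )

    def test_same_seed_identical_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(n=5), seed=11)
        b = generate_cohort(GeneratorConfig(n=5), seed=11)
        c = generate_cohort(GeneratorConfig(n=5), seed=12)
        for ra, rb in zip(a.subjects, b.subjects):
            assert ra == rb
        assert any(ra != rc for ra, rc in zip(a.subjects, c.subjects))

    def test_subject_draws_independent_of_cohort_size(self):
        small = generate_cohort(GeneratorConfig(n=3), seed=5)
        big = generate_cohort(GeneratorConfig(n=6), seed=5)
        for ra, rb in zip(small.subjects, big.subjects[:3]):
            assert ra == rb

    def test_marginals_within_configured_ranges(self):
        cfg = GeneratorConfig(n=200)
        cohort = generate_cohort(cfg, seed=21)
        far = np.array([r.far_acuity for r in cohort.subjects])
        letter_true = np.array(
            [r.true_params.peak_logcs for r in cohort.subjects]
        )
        assert far.min() >= cfg.acuity_range[0] and far.max() <= cfg.acuity_range[1]
        assert np.isfinite(letter_true).all()

    def test_generative_link_recovery_at_scale(self):
        """OLS of true peak logCS on letter CS recovers the configured link."""
        cfg = GeneratorConfig(n=200, letter_noise_sd=0.0)
        cohort = generate_cohort(cfg, seed=8)
        letter = np.array([r.letter_cs for r in cohort.subjects])
        peak = np.array([r.true_params.peak_logcs for r in cohort.subjects])
        reg = sps.linregress(letter, peak)
        assert abs(reg.slope - cfg.m_cs) < 3 * reg.stderr
        assert abs(reg.intercept - cfg.c_cs) < 3 * reg.intercept_stderr

    def test_invalid_config_lists_fields(self):
        cfg = GeneratorConfig(n=-1, sigma_cs=-0.5)
        with pytest.raises(ConfigError) as exc:
            generate_cohort(cfg, seed=0)
        assert "n" in exc.value.problems and "sigma_cs" in exc.value.problems


class TestSimulateSession:
    def test_noiseless_session_is_model_curve(self):
        p = CSFParams(1.8, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (1.5, 3.0, 6.0, 12.0), session_noise_sd=0.0)
        out = simulate_test_session(p, spec, seed=0)
        np.testing.assert_allclose(
            out, np.atleast_1d(evaluate_csf(p, np.array(spec.frequencies))), atol=1e-12
        )

    def test_retest_bias_applied_to_session_two_only(self):
        p = CSFParams(1.8, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (3.0, 6.0), session_noise_sd=0.0, retest_bias=0.1)
        s1 = simulate_test_session(p, spec, seed=0, session=1)
        s2 = simulate_test_session(p, spec, seed=0, session=2)
        np.testing.assert_allclose(s2 - s1, 0.1, atol=1e-12)

    def test_quantized_output_on_grid(self):
        p = CSFParams(1.8, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (3.0, 6.0, 12.0, 18.0), session_noise_sd=0.05,
                        quantization_levels=8)
        out = simulate_test_session(p, spec, seed=4)
        grids = spec.level_grids()
        for v, grid in zip(out, grids):
            assert np.min(np.abs(grid - v)) < 1e-12

    def test_noiseless_quantization_snaps_to_nearest_level(self):
        p = CSFParams(1.8, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (3.0, 6.0, 12.0, 18.0), session_noise_sd=0.0,
                        quantization_levels=8)
        out = simulate_test_session(p, spec, seed=0)
        curve = np.atleast_1d(evaluate_csf(p, np.array(spec.frequencies)))
        for v, c, grid in zip(out, curve, spec.level_grids()):
            c_clipped = min(max(c, grid[0]), spec.max_logcs)
            assert v == pytest.approx(grid[np.argmin(np.abs(grid - c_clipped))])

    def test_ceiling_clip(self):
        p = CSFParams(3.0, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (1.5, 3.0, 6.0), session_noise_sd=0.2)
        for seed in range(10):
            out = simulate_test_session(p, spec, seed=seed)
            assert np.all(out <= spec.max_logcs + 1e-12)

    def test_smooth_refit_yields_model_consistent_sessions(self):
        p = CSFParams(1.8, 4.0, 3.0, 0.3)
        spec = TestSpec("t", (1.5, 3.0, 6.0, 12.0, 18.0), session_noise_sd=0.1,
                        smooth_refit=True)
        out = simulate_test_session(p, spec, seed=7)
        # a second fit to the emitted vector reproduces it almost exactly
        from csfkit import fit_csf

        refit = fit_csf(list(zip(spec.frequencies, out)), seed=0)
        assert refit.rmse_fitted < 5e-3


class TestQuantizeChart:
    def test_value_on_level_unchanged(self):
        grid = [np.array([0.5, 1.0, 1.5])]
        assert quantize_chart([1.0], grid)[0] == 1.0

    def test_below_lowest_level_floors(self):
        grid = [np.array([0.5, 1.0, 1.5])]
        assert quantize_chart([-2.0], grid)[0] == 0.5

    def test_tie_goes_to_lower_sensitivity(self):
        grid = [np.array([1.0, 2.0])]
        assert quantize_chart([1.5], grid)[0] == 1.0

    def test_matches_brute_force_nearest_level(self):
        rng = np.random.default_rng(9)
        grid = np.sort(rng.uniform(0, 2.3, 8))
        for v in rng.uniform(-0.5, 3.0, 50):
            got = quantize_chart([v], [grid])[0]
            d = np.abs(grid - v)
            brute = np.min(grid[d <= d.min() + 1e-15])
            assert got == brute

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            quantize_chart([1.0], [np.array([])])


class TestRepeatabilityOrdering:
    def test_cor_ordering_tracks_configured_noise(self):
        """sine > chart > adaptive repeatability ordering, seeded replicates."""
        wins = 0
        reps = 12
        for rep in range(reps):
            cohort = generate_cohort(GeneratorConfig(n=43), seed=3000 + rep)
            cors = {}
            for tid, spec in cohort.test_specs.items():
                per_freq = []
                for j in range(len(spec.frequencies)):
                    s1 = [r.csf_sessions[tid][0][j] for r in cohort.subjects]
                    s2 = [r.csf_sessions[tid][1][j] for r in cohort.subjects]
                    per_freq.append(bland_altman(s1, s2).cor)
                cors[tid] = float(np.mean(per_freq))
            if cors["csf_sine"] > cors["csf_csv1000"] > cors["csf_qcsf"]:
                wins += 1
        assert wins >= reps - 1
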