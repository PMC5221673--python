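"""Synthetic clinical cohorts for contrast-sensitivity analysis.

Generates seeded cohorts with the statistical structure the analysis
pipeline assumes: per-subject auxiliary measures (high-contrast acuity in
logMAR, broadband letter contrast sensitivity in logCS), ground-truth
truncated log-parabola CSF parameters tied to those measures through linear
links, and two-session frequency-specific logCS measurements for up to
three CSF test styles:

* a computerised sine-grating test (five frequencies 1.5-18 c/deg,
  continuous logCS output, relatively high session noise),
* a printed chart test (four frequencies 3-18 c/deg with only eight
  discrete contrast levels per frequency),
* an adaptive test whose report is itself a fitted curve, which smooths
  across frequencies (toggleable refit-smoothing).

The generator emulates the *outputs* of these instruments statistically; it
does not simulate trial-by-trial psychophysics (staircases, Bayesian
adaptive placement, lapses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import CSFParams, evaluate_csf

__all__ = [
    "TestSpec",
    "SubjectRecord",
    "CohortDataset",
    "GeneratorConfig",
    "ConfigError",
    "default_test_specs",
    "generate_cohort",
    "simulate_test_session",
    "quantize_chart",
    "matched_noise_config",
    "zero_noise_config",
]


class ConfigError(ValueError):
    """Invalid generator configuration; carries the offending field names."""

    def __init__(self, problems: dict[str, str]):
        self.problems = problems
        msg = "; ".join(f"{k}: {v}" for k, v in sorted(problems.items()))
        super().__init__(f"invalid generator configuration -- {msg}")


@dataclass(frozen=True)
class TestSpec:
    """Measurement characteristics of one CSF test instrument.

    ``session_noise_sd`` is the i.i.d. Gaussian noise added to each
    frequency-specific logCS value per session; ``retest_bias`` is added to
    session 2 only (practice effect).  ``quantization_levels``, when set,
    snaps outputs to a per-frequency grid of discrete logCS levels (chart
    tests); ``smooth_refit`` re-fits the model to the noisy samples and
    emits the fitted curve instead (adaptive tests).  ``min_contrast`` is
    the lowest displayable contrast (proportion), which caps logCS at
    ``log10(1/min_contrast)``.
    """

    test_id: str
    frequencies: tuple[float, ...]
    session_noise_sd: float = 0.1
    retest_bias: float = 0.0
    quantization_levels: int | None = None
    min_contrast: float = 0.005
    smooth_refit: bool = False
    chart_grid: tuple[tuple[float, ...], ...] | None = None
    grid_span_logcs: float = 0.9

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if not freqs or any(f <= 0 for f in freqs) or list(freqs) != sorted(freqs):
            raise ValueError("frequencies must be positive and ascending")
        if self.session_noise_sd < 0:
            raise ValueError("session_noise_sd must be >= 0")
        if not (0 < self.min_contrast < 1):
            raise ValueError("min_contrast must be in (0, 1)")
        object.__setattr__(self, "frequencies", freqs)

    @property
    def max_logcs(self) -> float:
        """Ceiling on logCS implied by the lowest displayable contrast."""
        return -math.log10(self.min_contrast)

    def level_grids(self) -> list[np.ndarray]:
        """Per-frequency logCS level grids for quantized (chart) tests.

        Default: ``quantization_levels`` equally spaced logCS levels per
        frequency, running down from the ceiling over ``grid_span_logcs``
        (i.e. log-spaced contrast levels from ``min_contrast`` upward).
        """
        if self.chart_grid is not None:
            return [np.asarray(g, dtype=float) for g in self.chart_grid]
        if self.quantization_levels is None:
            raise ValueError(f"test {self.test_id!r} is not quantized")
        levels = np.linspace(
            self.max_logcs - self.grid_span_logcs, self.max_logcs,
            self.quantization_levels,
        )
        return [levels for _ in self.frequencies]


def default_test_specs() -> dict[str, TestSpec]:
    """The three emulated instruments with default noise characteristics.

    Session noise SDs (0.18 / 0.12 / 0.08 logCS) are set so that the implied
    coefficients of repeatability, COR = 1.96 * sqrt(2) * sigma, fall in the
    ranges published for these instrument classes (roughly 0.5 / 0.33 / 0.22
    logCS), preserving the characteristic ordering sine > chart > adaptive.
    """
    return {
        "csf_sine": TestSpec(
            "csf_sine", (1.5, 3.0, 6.0, 12.0, 18.0),
            session_noise_sd=0.18, retest_bias=0.05,
        ),
        "csf_csv1000": TestSpec(
            "csf_csv1000", (3.0, 6.0, 12.0, 18.0),
            session_noise_sd=0.12, retest_bias=0.05, quantization_levels=8,
        ),
        "csf_qcsf": TestSpec(
            "csf_qcsf", (1.5, 3.0, 6.0, 12.0, 18.0),
            session_noise_sd=0.08, retest_bias=0.05, smooth_refit=True,
        ),
    }


@dataclass
class SubjectRecord:
    """One subject's auxiliary measures and per-test session data.

    Frequency-specific logCS vectors are stored as tuples aligned with the
    owning :class:`TestSpec`'s frequencies; ``csf_sessions[test_id]`` holds
    one tuple per session.  ``true_params`` is populated for synthetic
    subjects only.
    """

    id: str
    age: float
    disease_flag: bool
    far_acuity: float
    near_acuity: float
    letter_cs_sessions: tuple[float, ...]
    csf_sessions: dict[str, tuple[tuple[float, ...], ...]]
    true_params: CSFParams | None = None
    notes: tuple[str, ...] = ()

    @property
    def letter_cs(self) -> float:
        """Session-averaged letter contrast sensitivity (logCS)."""
        return float(np.mean(self.letter_cs_sessions))

    def csf_logcs(self, test_id: str) -> np.ndarray:
        """Session-averaged logCS vector for one test."""
        sessions = self.csf_sessions[test_id]
        return np.mean([np.asarray(s, dtype=float) for s in sessions], axis=0)

    def n_sessions(self, test_id: str) -> int:
        return len(self.csf_sessions[test_id])


@dataclass
class CohortDataset:
    """A set of subject records plus the test specs that shaped them."""

    subjects: list[SubjectRecord]
    test_specs: dict[str, TestSpec]
    config: "GeneratorConfig | None" = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for rec in self.subjects:
            for test_id, sessions in rec.csf_sessions.items():
                if test_id not in self.test_specs:
                    raise ValueError(
                        f"subject {rec.id}: unknown test {test_id!r}"
                    )
                nf = len(self.test_specs[test_id].frequencies)
                for sess in sessions:
                    if len(sess) != nf:
                        raise ValueError(
                            f"subject {rec.id}, test {test_id}: session vector "
                            f"length {len(sess)} != {nf} frequencies"
                        )

    @property
    def n(self) -> int:
        return len(self.subjects)

    def test_ids(self) -> list[str]:
        return list(self.test_specs)

    def subject(self, subject_id: str) -> SubjectRecord:
        for rec in self.subjects:
            if rec.id == subject_id:
                return rec
        raise KeyError(subject_id)


@dataclass
class GeneratorConfig:
    """Distributional recipe for a synthetic cohort.

    The linear links tie each subject's ground-truth CSF peak to their
    auxiliary measures: ``peak_logcs = m_cs * letter_cs + c_cs + N(0,
    sigma_cs)`` and ``log10(peak_sf) = m_sf * far_acuity + c_sf + N(0,
    sigma_sf)``.  Bandwidth and truncation are drawn around the template
    values ``beta_t`` / ``delta_t``.  Acuity and letter CS marginals follow
    the mildly impaired clinical range the pipeline targets (far acuity
    -0.3 to 0.34 logMAR; letter CS mean 1.57, SD 0.25 logCS).
    """

    n: int = 43
    # linear links and template shape (configuration, not empirical claims)
    m_cs: float = 0.8
    c_cs: float = 0.7
    m_sf: float = -1.0
    c_sf: float = 0.6
    beta_t: float = 3.0
    delta_t: float = 0.4
    sigma_cs: float = 0.1
    sigma_sf: float = 0.1
    sigma_beta: float = 0.1
    sigma_delta: float = 0.1
    # auxiliary-measure marginals
    acuity_mean: float = -0.05
    acuity_sd: float = 0.12
    acuity_range: tuple[float, float] = (-0.3, 0.34)
    near_offset_sd: float = 0.05
    letter_cs_mean: float = 1.57
    letter_cs_sd: float = 0.25
    letter_cs_range: tuple[float, float] = (0.5, 2.25)
    letter_noise_sd: float = 0.14
    letter_retest_bias: float = 0.01
    # demographics
    p_disease: float = 14.0 / 43.0
    age_mean_healthy: float = 36.0
    age_sd_healthy: float = 10.5
    age_mean_disease: float = 57.7
    age_sd_disease: float = 16.6
    sessions: int = 2
    tests: dict[str, TestSpec] = field(default_factory=default_test_specs)

    def validate(self) -> None:
        problems: dict[str, str] = {}
        if self.n < 0:
            problems["n"] = "must be >= 0"
        for name in ("sigma_cs", "sigma_sf", "sigma_beta", "sigma_delta",
                     "letter_noise_sd", "acuity_sd", "letter_cs_sd",
                     "near_offset_sd"):
            if getattr(self, name) < 0:
                problems[name] = "must be >= 0"
        if not (0 <= self.p_disease <= 1):
            problems["p_disease"] = "must be in [0, 1]"
        if self.sessions not in (1, 2):
            problems["sessions"] = "must be 1 or 2"
        if self.acuity_range[0] >= self.acuity_range[1]:
            problems["acuity_range"] = "low bound must be below high bound"
        if self.letter_cs_range[0] >= self.letter_cs_range[1]:
            problems["letter_cs_range"] = "low bound must be below high bound"
        if self.beta_t <= 0:
            problems["beta_t"] = "must be > 0"
        if self.delta_t < 0:
            problems["delta_t"] = "must be >= 0"
        if not self.tests:
            problems["tests"] = "at least one test spec required"
        if problems:
            raise ConfigError(problems)


def zero_noise_config(
    n: int = 20, c_sf: float = 1.0, c_cs: float = 0.35, **overrides
) -> GeneratorConfig:
    """Config with exact linear links, constant shape, and no noise.

    The intercepts are chosen so the generated curves are fully expressed
    in the emitted data: ``c_sf`` defaults to 1.0 so every subject's peak
    sits above ~4.6 c/deg and the truncation plateau covers the lowest
    sampled frequency (keeping all four parameters identifiable), and
    ``c_cs`` defaults to 0.35 so peak logCS stays below the instruments'
    2.3-logCS ceiling (no clipping).
    """
    tests = {
        tid: replace(spec, session_noise_sd=0.0, retest_bias=0.0,
                     quantization_levels=None, smooth_refit=False)
        for tid, spec in default_test_specs().items()
    }
    cfg = GeneratorConfig(
        n=n, c_sf=c_sf, c_cs=c_cs, sigma_cs=0.0, sigma_sf=0.0, sigma_beta=0.0,
        sigma_delta=0.0, letter_noise_sd=0.0, letter_retest_bias=0.0,
        tests=tests,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def matched_noise_config(n: int = 43) -> GeneratorConfig:
    """Sine-test configuration whose prediction error matches retest error.

    Between-subject scatter (sigma_cs = 0.17, sigma_sf = 0.12) is set from
    the error-budget identity E[mean e^2] ~= sigma^2/2 + V_pred so that the
    leave-one-out prediction RMSE of the sine test lands in the same range
    as its test-retest RMSE (~0.23 vs ~0.25 logCS), the regime the
    predictive framework targets.
    """
    return GeneratorConfig(
        n=n,
        sigma_cs=0.17,
        sigma_sf=0.12,
        tests={"csf_sine": default_test_specs()["csf_sine"]},
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float) -> float:
    """Truncated-normal draw by rejection; degenerate sd returns the mean."""
    if sd == 0:
        return float(min(max(mean, low), high))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def quantize_chart(values, grids: Sequence[Sequence[float]]) -> np.ndarray:
    """Snap logCS values to per-frequency chart level grids.

    Each value maps to the nearest level of its frequency's ascending grid,
    with exact ties resolved toward the lower level (lower sensitivity).
    Values below the lowest level floor at the lowest level.
    """
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if len(grids) != vals.size:
        raise ValueError("need one level grid per value")
    out = np.empty_like(vals)
    for i, (v, grid) in enumerate(zip(vals, grids)):
        levels = np.asarray(grid, dtype=float)
        if levels.size == 0:
            raise ValueError("empty chart level grid")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("chart level grids must be strictly ascending")
        d = np.abs(levels - v)
        best = np.min(d)
        out[i] = float(np.min(levels[d <= best + 1e-15]))
    return out


def simulate_test_session(
    true_params: CSFParams,
    spec: TestSpec,
    seed: int | np.random.Generator | None = None,
    session: int = 1,
) -> np.ndarray:
    """Emulate one session of a CSF test for a known underlying CSF.

    Evaluates the true curve at the test's frequencies, adds the retest
    bias (session 2 only) and i.i.d. session noise, clips to the
    instrument's displayable range [0, max_logcs], applies refit smoothing
    for adaptive-style tests, and quantizes to the chart grid if the test
    is discrete.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sfs = np.asarray(spec.frequencies, dtype=float)
    y = np.atleast_1d(evaluate_csf(true_params, sfs)).astype(float)
    if session == 2:
        y = y + spec.retest_bias
    if spec.session_noise_sd > 0:
        y = y + rng.normal(0.0, spec.session_noise_sd, size=y.size)
    y = np.clip(y, 0.0, spec.max_logcs)
    if spec.smooth_refit:
        from .fitting import fit_csf

        # single data-driven start: the refit only needs a smooth curve
        # through the noisy samples, not a certified global optimum
        fit = fit_csf(list(zip(sfs, y)), seed=int(rng.integers(2**31)),
                      n_restarts=1)
        y = np.atleast_1d(evaluate_csf(fit.params, sfs)).astype(float)
        y = np.clip(y, 0.0, spec.max_logcs)
    if spec.quantization_levels is not None or spec.chart_grid is not None:
        y = quantize_chart(y, spec.level_grids())
    return y


def generate_cohort(config: GeneratorConfig, seed: int) -> CohortDataset:
    """Draw a fully reproducible synthetic cohort.

    A per-subject substream keyed by ``(seed, subject index)`` drives all of
    that subject's draws, so cohorts are independent of generation order and
    bit-identical for a given seed.
    """
    config.validate()
    subjects: list[SubjectRecord] = []
    for i in range(config.n):
        rng = np.random.default_rng([seed, i])
        diseased = bool(rng.random() < config.p_disease)
        if diseased:
            age = _trunc_normal(rng, config.age_mean_disease, config.age_sd_disease, 22, 90)
        else:
            age = _trunc_normal(rng, config.age_mean_healthy, config.age_sd_healthy, 22, 90)
        far = _trunc_normal(rng, config.acuity_mean, config.acuity_sd, *config.acuity_range)
        near = far + (rng.normal(0.0, config.near_offset_sd) if config.near_offset_sd > 0 else 0.0)
        letter_true = _trunc_normal(
            rng, config.letter_cs_mean, config.letter_cs_sd, *config.letter_cs_range
        )
        letter_sessions = []
        for sess in range(config.sessions):
            v = letter_true + (config.letter_retest_bias if sess == 1 else 0.0)
            if config.letter_noise_sd > 0:
                v += rng.normal(0.0, config.letter_noise_sd)
            letter_sessions.append(float(v))

        peak_logcs = config.m_cs * letter_true + config.c_cs
        if config.sigma_cs > 0:
            peak_logcs += rng.normal(0.0, config.sigma_cs)
        log_peak_sf = config.m_sf * far + config.c_sf
        if config.sigma_sf > 0:
            log_peak_sf += rng.normal(0.0, config.sigma_sf)
        beta = _trunc_normal(rng, config.beta_t, config.sigma_beta, 0.5, 8.0)
        delta = _trunc_normal(rng, config.delta_t, config.sigma_delta, 0.0, 2.0)
        truth = CSFParams(
            peak_logcs=float(peak_logcs),
            peak_sf=float(10.0 ** log_peak_sf),
            bandwidth_oct=float(beta),
            truncation=float(delta),
        )

        csf_sessions: dict[str, tuple[tuple[float, ...], ...]] = {}
        for test_id, spec in config.tests.items():
            sessions = []
            for sess in range(config.sessions):
                vec = simulate_test_session(truth, spec, seed=rng, session=sess + 1)
                sessions.append(tuple(float(v) for v in vec))
            csf_sessions[test_id] = tuple(sessions)

        subjects.append(
            SubjectRecord(
                id=f"S{i + 1:03d}",
                age=age,
                disease_flag=diseased,
                far_acuity=far,
                near_acuity=float(near),
                letter_cs_sessions=tuple(letter_sessions),
                csf_sessions=csf_sessions,
                true_params=truth,
            )
        )
    return CohortDataset(
        subjects=subjects, test_specs=dict(config.tests), config=config, seed=seed
    )
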