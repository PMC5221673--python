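"""Cohort file I/O, orchestration, and report generation.

The on-disk cohort format is a long delimited table with one row per
(subject, measure, session, frequency): columns ``subject_id, age,
disease_flag, measure_type, session, sf, value, value_units``.
``measure_type`` is one of the CSF test ids (``csf_sine``, ``csf_csv1000``,
``csf_qcsf`` or any id declared in the supplied test specs), ``letter_cs``,
``acuity_far`` or ``acuity_near``; ``sf`` is empty for non-CSF rows.
Write -> read round-trips are lossless for the measured data.

:func:`run_pipeline` chains the full analysis: session averaging, per
subject full fits, Bland-Altman repeatability, partial-model analysis,
correlations, template estimation with leave-one-out evaluation, and
group-comparison statistics, bundled into an :class:`AnalysisReport` whose
regeneration from the same inputs and seed is bit-identical.

Significance stars follow the 0.05/0.01 convention; no multiple-testing
correction is applied anywhere in the report -- every p-value is raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    CohortDataset,
    GeneratorConfig,
    SubjectRecord,
    TestSpec,
    default_test_specs,
    generate_cohort,
)
from .fitting import PARAM_NAMES, FitResult, PartialModelResult, partial_model_analysis
from .model import aulcsf
from .repeatability import bland_altman
from .template import (
    CSFTemplate,
    PredictionEvaluation,
    correlation_table,
    estimate_template,
    fit_cohort,
    loo_evaluate,
)

__all__ = [
    "AUX_MEASURES",
    "AnalysisReport",
    "PipelineConfig",
    "read_cohort",
    "write_cohort",
    "group_comparison_stats",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger(__name__)

AUX_MEASURES = ("letter_cs", "acuity_far", "acuity_near")
COLUMNS = [
    "subject_id",
    "age",
    "disease_flag",
    "measure_type",
    "session",
    "sf",
    "value",
    "value_units",
]


def write_cohort(cohort: CohortDataset, path) -> None:
    """Write a cohort to the long-format delimited schema."""
    rows = []
    for rec in cohort.subjects:
        base = {
            "subject_id": rec.id,
            "age": rec.age,
            "disease_flag": int(rec.disease_flag),
        }
        for sess, v in enumerate(rec.letter_cs_sessions, start=1):
            rows.append(
                base
                | {"measure_type": "letter_cs", "session": sess, "sf": np.nan,
                   "value": v, "value_units": "logCS"}
            )
        rows.append(
            base
            | {"measure_type": "acuity_far", "session": 1, "sf": np.nan,
               "value": rec.far_acuity, "value_units": "logMAR"}
        )
        rows.append(
            base
            | {"measure_type": "acuity_near", "session": 1, "sf": np.nan,
               "value": rec.near_acuity, "value_units": "logMAR"}
        )
        for test_id, sessions in rec.csf_sessions.items():
            freqs = cohort.test_specs[test_id].frequencies
            for sess, vec in enumerate(sessions, start=1):
                for sf, v in zip(freqs, vec):
                    rows.append(
                        base
                        | {"measure_type": test_id, "session": sess, "sf": sf,
                           "value": v, "value_units": "logCS"}
                    )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_cohort(path, test_specs: dict[str, TestSpec] | None = None) -> CohortDataset:
    """Read a cohort from the long-format delimited schema.

    Schema violations (unknown measure type, non-positive frequency on a
    CSF row, bad session label) are reported with the offending row
    numbers.  Row order in the file is irrelevant.  ``test_specs`` supplies
    instrument metadata for the CSF measure types; the three standard test
    ids fall back to their defaults, and any other id must be declared.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")

    known_specs = dict(default_test_specs())
    if test_specs:
        known_specs.update(test_specs)
    aux = set(AUX_MEASURES)

    csf_types = sorted(
        t for t in df["measure_type"].unique() if t not in aux
    )
    for t in csf_types:
        if t not in known_specs:
            rows = df.index[df["measure_type"] == t].tolist()
            raise ValueError(
                f"unknown measure_type {t!r} (rows {rows[:10]}); declare it "
                f"via test_specs or use one of {sorted(known_specs) + list(aux)}"
            )

    bad_sessions = df.index[~df["session"].isin([1, 2])].tolist()
    if bad_sessions:
        raise ValueError(f"session must be 1 or 2; bad rows: {bad_sessions[:10]}")
    is_csf = df["measure_type"].isin(csf_types)
    bad_sf = df.index[is_csf & ~(df["sf"] > 0)].tolist()
    if bad_sf:
        raise ValueError(
            f"CSF rows require a positive sf; bad rows: {bad_sf[:10]}"
        )

    subjects = []
    specs_used: dict[str, TestSpec] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        age = float(grp["age"].iloc[0])
        disease = bool(grp["disease_flag"].iloc[0])

        def _aux(measure: str, grp=grp, sid=sid) -> list[float]:
            sub = grp[grp["measure_type"] == measure].sort_values("session")
            return [float(v) for v in sub["value"]]

        letter = _aux("letter_cs")
        far = _aux("acuity_far")
        near = _aux("acuity_near")
        if not letter or not far or not near:
            raise ValueError(
                f"subject {sid}: missing letter_cs or acuity rows"
            )
        csf_sessions: dict[str, tuple[tuple[float, ...], ...]] = {}
        for t in csf_types:
            sub = grp[grp["measure_type"] == t]
            if sub.empty:
                continue
            spec = known_specs[t]
            freqs_present = tuple(sorted(sub["sf"].unique()))
            if set(freqs_present) - set(spec.frequencies):
                spec = replace(spec, frequencies=freqs_present)
            specs_used[t] = spec
            sessions = []
            for sess in sorted(sub["session"].unique()):
                ss = sub[sub["session"] == sess].sort_values("sf")
                if tuple(ss["sf"]) != spec.frequencies:
                    raise ValueError(
                        f"subject {sid}, test {t}, session {sess}: frequencies "
                        f"{tuple(ss['sf'])} do not match spec {spec.frequencies}"
                    )
                sessions.append(tuple(float(v) for v in ss["value"]))
            csf_sessions[t] = tuple(sessions)
        subjects.append(
            SubjectRecord(
                id=str(sid),
                age=age,
                disease_flag=disease,
                far_acuity=far[0],
                near_acuity=near[0],
                letter_cs_sessions=tuple(letter),
                csf_sessions=csf_sessions,
            )
        )
    for t in csf_types:
        specs_used.setdefault(t, known_specs[t])
    return CohortDataset(subjects=subjects, test_specs=specs_used)


# ---------------------------------------------------------------------------
# Group comparison statistics (routine formulas, included for report parity)
# ---------------------------------------------------------------------------


def group_comparison_stats(
    cohort: CohortDataset,
    fits_by_test: dict[str, dict[str, FitResult]],
    evaluations: dict[str, PredictionEvaluation] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of each fitted quantity across tests, plus paired t's.

    Standard-formula statistics reported for completeness: F across the
    test types for the four parameters and the AULCSF, and -- when
    leave-one-out evaluations are supplied -- the paired t of prediction
    RMSE against test-retest RMSE per test.
    """
    test_ids = list(fits_by_test)
    if len(test_ids) < 2:
        raise ValueError("group comparison requires fits for >= 2 tests")
    rows = []
    quantities = list(PARAM_NAMES) + ["aulcsf"]
    for q in quantities:
        groups = []
        for t in test_ids:
            fits = fits_by_test[t]
            spec = cohort.test_specs[t]
            if q == "aulcsf":
                vals = [
                    aulcsf(f.params, spec.frequencies[0], spec.frequencies[-1])
                    for f in fits.values()
                ]
            else:
                vals = [getattr(f.params, q) for f in fits.values()]
            groups.append(np.asarray(vals, dtype=float))
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = sps.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(len(g) for g in groups) - len(groups)
        rows.append(
            {"statistic": "anova_F", "quantity": q, "value": float(f_stat),
             "df1": df1, "df2": df2, "p": float(p)}
        )
    if evaluations:
        for t, ev in evaluations.items():
            if "t_predicted_vs_test_retest" in ev.summary:
                rows.append(
                    {
                        "statistic": "paired_t_predicted_vs_test_retest",
                        "quantity": t,
                        "value": ev.summary["t_predicted_vs_test_retest"],
                        "df1": ev.summary.get("df", np.nan),
                        "df2": np.nan,
                        "p": ev.summary["p_predicted_vs_test_retest"],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """What to analyse: a cohort file, or a generator recipe, plus a seed."""

    seed: int = 0
    cohort_path: str | None = None
    generator: GeneratorConfig | None = None
    tests: list[str] | None = None
    run_partial_models: bool = True
    run_predictions: bool = True


@dataclass
class AnalysisReport:
    """Bundle of every table the analysis produces."""

    seed: int
    cohort_n: int
    repeatability: pd.DataFrame | None
    parameters: pd.DataFrame
    correlations: pd.DataFrame
    templates: dict[str, CSFTemplate]
    partial_models: dict[str, PartialModelResult]
    predictions: dict[str, PredictionEvaluation]
    group_stats: pd.DataFrame | None
    config_echo: str = ""


def _repeatability_table(cohort: CohortDataset) -> pd.DataFrame | None:
    """Bland-Altman COR/bias per measure (test x frequency, and letter CS)."""
    rows = []
    two_session = [
        rec for rec in cohort.subjects if len(rec.letter_cs_sessions) >= 2
    ]
    if len(two_session) >= 2:
        res = bland_altman(
            [r.letter_cs_sessions[0] for r in two_session],
            [r.letter_cs_sessions[1] for r in two_session],
            measure_id="letter_cs",
        )
        rows.append(res)
    for test_id, spec in cohort.test_specs.items():
        recs = [
            r for r in cohort.subjects
            if test_id in r.csf_sessions and len(r.csf_sessions[test_id]) >= 2
        ]
        if len(recs) < 2:
            continue
        for j, sf in enumerate(spec.frequencies):
            res = bland_altman(
                [r.csf_sessions[test_id][0][j] for r in recs],
                [r.csf_sessions[test_id][1][j] for r in recs],
                measure_id=f"{test_id}@{sf:g}",
            )
            rows.append(res)
    if not rows:
        return None
    return pd.DataFrame(
        [
            {"measure": r.measure_id, "cor": r.cor, "bias": r.bias, "n": r.n}
            for r in rows
        ]
    )


def _parameter_table(
    cohort: CohortDataset, fits_by_test: dict[str, dict[str, FitResult]]
) -> pd.DataFrame:
    """Group mean (SD) of the four parameters and AULCSF per test."""
    rows = []
    for test_id, fits in fits_by_test.items():
        spec = cohort.test_specs[test_id]
        vals = {q: [getattr(f.params, q) for f in fits.values()] for q in PARAM_NAMES}
        vals["aulcsf"] = [
            aulcsf(f.params, spec.frequencies[0], spec.frequencies[-1])
            for f in fits.values()
        ]
        vals["rmse_fitted"] = [f.rmse_fitted for f in fits.values()]
        for q, v in vals.items():
            arr = np.asarray(v, dtype=float)
            rows.append(
                {"test_id": test_id, "quantity": q,
                 "mean": float(arr.mean()),
                 "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                 "n": int(arr.size)}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis chain and bundle the report."""
    if config.cohort_path is not None:
        log.info("stage load: reading cohort from %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path)
    else:
        gen = config.generator or GeneratorConfig()
        log.info("stage simulate: generating synthetic cohort (n=%d, seed=%d)",
                 gen.n, config.seed)
        cohort = generate_cohort(gen, seed=config.seed)
    test_ids = config.tests or cohort.test_ids()
    seed = config.seed

    log.info("stage fit: full four-parameter fits for %d tests", len(test_ids))
    fits_by_test = {}
    for t in test_ids:
        try:
            fits_by_test[t] = fit_cohort(cohort, t, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage fit failed for test {t}: {exc}") from exc

    log.info("stage repeatability")
    repeatability = _repeatability_table(cohort)

    parameters = _parameter_table(cohort, fits_by_test)

    log.info("stage partial models")
    partial_models: dict[str, PartialModelResult] = {}
    if config.run_partial_models and cohort.n >= 2:
        for t in test_ids:
            partial_models[t] = partial_model_analysis(cohort, t, seed=seed)

    log.info("stage correlations")
    correlations = correlation_table(cohort, test_ids, fits_by_test=fits_by_test)

    log.info("stage templates + leave-one-out")
    templates: dict[str, CSFTemplate] = {}
    predictions: dict[str, PredictionEvaluation] = {}
    complete = [
        rec.id for rec in cohort.subjects
        if np.isfinite(rec.letter_cs) and np.isfinite(rec.far_acuity)
    ]
    if len(complete) < cohort.n:
        log.info("excluding %d subjects lacking letter CS or far acuity",
                 cohort.n - len(complete))
    if config.run_predictions:
        for t in test_ids:
            templates[t] = estimate_template(cohort, t, fits=fits_by_test[t])
            predictions[t] = loo_evaluate(cohort, t, seed=seed)

    group_stats = None
    if len(test_ids) >= 2:
        group_stats = group_comparison_stats(cohort, fits_by_test, predictions or None)

    return AnalysisReport(
        seed=seed,
        cohort_n=cohort.n,
        repeatability=repeatability,
        parameters=parameters,
        correlations=correlations,
        templates=templates,
        partial_models=partial_models,
        predictions=predictions,
        group_stats=group_stats,
        config_echo=repr(config),
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the report bundle as delimited text files (deterministic bytes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    if report.repeatability is not None:
        report.repeatability.to_csv(out / "repeatability.csv", index=False,
                                    float_format=fmt)
    report.parameters.to_csv(out / "parameters.csv", index=False, float_format=fmt)
    report.correlations.to_csv(out / "correlations.csv", index=False, float_format=fmt)
    for t, template in report.templates.items():
        template.to_file(out / f"template_{t}.txt")
    for t, pm in report.partial_models.items():
        pm.summary.to_csv(out / f"partial_models_{t}.csv", float_format=fmt)
    for t, ev in report.predictions.items():
        ev.per_subject.to_csv(out / f"prediction_{t}.csv", float_format=fmt)
    if report.group_stats is not None:
        report.group_stats.to_csv(out / "group_stats.csv", index=False,
                                  float_format=fmt)
    lines = [
        "analysis report",
        f"seed: {report.seed}",
        f"subjects: {report.cohort_n}",
        f"config: {report.config_echo}",
        "note: p-values are raw; no multiple-testing correction is applied.",
    ]
    for t, ev in report.predictions.items():
        lines.append(
            f"{t}: mean rmse_predicted={ev.summary.get('mean_rmse_predicted', float('nan')):.4f} "
            f"mean rmse_fitted={ev.summary.get('mean_rmse_fitted', float('nan')):.4f} "
            f"mean rmse_test_retest={ev.summary.get('mean_rmse_test_retest', float('nan')):.4f}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
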