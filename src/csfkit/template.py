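"""Normative-template estimation and zero-free-parameter CSF prediction.

The predictive model holds that individuals differ mainly in the height and
lateral position of an otherwise standard-shaped CSF.  A test-specific
template is summarised by six numbers estimated from a normative cohort:

* ``beta_t``, ``delta_t`` -- group-mean bandwidth (octaves) and truncation
  depth (logCS) from per-subject full four-parameter fits;
* ``m_cs``, ``c_cs`` -- slope and intercept of the ordinary least-squares
  regression of fitted peak logCS on measured letter CS (logCS);
* ``m_sf``, ``c_sf`` -- slope and intercept of the OLS regression of fitted
  log10 peak spatial frequency on far acuity (logMAR); the slope is
  expected negative (better acuity, higher peak frequency).

Given the template, predicting a new subject's full CSF is deterministic:
plug their letter CS and far acuity into the two linear links and attach
the template bandwidth and truncation -- zero free parameters per subject.
Evaluation is leave-one-out: each subject is predicted from a template
estimated on everyone else, and the prediction RMSE at the test's sampled
frequencies is benchmarked against the full-fit RMSE (lower bound within
the model family) and the subject's own test-retest RMSE (the
repeatability of the instrument itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitResult, fit_csf, rmse
from .model import CSFParams, aulcsf, evaluate_csf, high_sf_cutoff
from .repeatability import average_sessions, rmse_test_retest

__all__ = [
    "CSFTemplate",
    "PredictionEvaluation",
    "fit_cohort",
    "estimate_template",
    "predict_subject_csf",
    "loo_evaluate",
    "correlation_table",
]


@dataclass(frozen=True)
class CSFTemplate:
    """Six normative-group numbers that map (letter CS, acuity) to a CSF."""

    test_id: str
    beta_t: float
    delta_t: float
    m_cs: float
    c_cs: float
    m_sf: float
    c_sf: float
    n_subjects: int = 0
    stderr: Mapping[str, float] | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_t": self.beta_t,
            "delta_t": self.delta_t,
            "m_cs": self.m_cs,
            "c_cs": self.c_cs,
            "m_sf": self.m_sf,
            "c_sf": self.c_sf,
        }

    def to_file(self, path) -> None:
        """Serialize as a small keyed text file."""
        import datetime

        lines = [f"test_id: {self.test_id}"]
        lines += [f"{k}: {v!r}" for k, v in self.as_dict().items()]
        lines.append(f"n_subjects: {self.n_subjects}")
        lines.append(f"date: {datetime.date.today().isoformat()}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "CSFTemplate":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if ":" in line:
                    k, v = line.split(":", 1)
                    kv[k.strip()] = v.strip()
        return cls(
            test_id=kv["test_id"],
            beta_t=float(kv["beta_t"]),
            delta_t=float(kv["delta_t"]),
            m_cs=float(kv["m_cs"]),
            c_cs=float(kv["c_cs"]),
            m_sf=float(kv["m_sf"]),
            c_sf=float(kv["c_sf"]),
            n_subjects=int(kv.get("n_subjects", 0)),
        )


@dataclass
class PredictionEvaluation:
    """Leave-one-out prediction errors benchmarked against fit and retest.

    ``per_subject`` columns: rmse_predicted, rmse_fitted, rmse_test_retest
    (all logCS; the latter NaN when no retest session exists).  ``summary``
    holds group means/SDs and the paired t of predicted vs test-retest.
    """

    test_id: str
    per_subject: pd.DataFrame
    summary: dict[str, float] = field(default_factory=dict)
    templates: dict[str, CSFTemplate] = field(default_factory=dict)


def fit_cohort(cohort, test_id: str, seed: int = 0) -> dict[str, FitResult]:
    """Full four-parameter fits to each subject's session-averaged data."""
    spec = cohort.test_specs[test_id]
    sfs = np.asarray(spec.frequencies, dtype=float)
    fits: dict[str, FitResult] = {}
    for rec in cohort.subjects:
        avg = average_sessions(rec)
        fits[rec.id] = fit_csf(list(zip(sfs, avg.csf_logcs(test_id))), seed=seed)
    return fits


def _template_from_fits(
    test_id: str,
    fits: Mapping[str, FitResult],
    letter_cs: Mapping[str, float],
    far_acuity: Mapping[str, float],
) -> CSFTemplate:
    ids = list(fits)
    if len(ids) < 3:
        raise ValueError(f"template estimation requires >= 3 subjects, got {len(ids)}")
    letter = np.array([letter_cs[i] for i in ids])
    acuity = np.array([far_acuity[i] for i in ids])
    for name, x in (("letter CS", letter), ("far acuity", acuity)):
        if np.all(x == x[0]):
            raise ValueError(f"zero variance in predictor {name}; links are undefined")
    peak_logcs = np.array([fits[i].params.peak_logcs for i in ids])
    log_peak_sf = np.array([math.log10(fits[i].params.peak_sf) for i in ids])
    betas = np.array([fits[i].params.bandwidth_oct for i in ids])
    # truncation is only informative for subjects whose plateau was actually
    # expressed in the data; floor-snapped (unidentified) deltas would bias
    # the template mean downward, so use the identified subset when present
    delta_ids = [i for i in ids if getattr(fits[i], "delta_identifiable", True)]
    if not delta_ids:
        delta_ids = ids
    deltas = np.array([fits[i].params.truncation for i in delta_ids])

    reg_cs = sps.linregress(letter, peak_logcs)
    reg_sf = sps.linregress(acuity, log_peak_sf)
    n = len(ids)
    stderr = {
        "beta_t": float(np.std(betas, ddof=1) / math.sqrt(n)),
        "delta_t": float(
            np.std(deltas, ddof=1) / math.sqrt(len(deltas))
            if len(deltas) > 1 else float("nan")
        ),
        "m_cs": float(reg_cs.stderr),
        "c_cs": float(reg_cs.intercept_stderr),
        "m_sf": float(reg_sf.stderr),
        "c_sf": float(reg_sf.intercept_stderr),
    }
    return CSFTemplate(
        test_id=test_id,
        beta_t=float(np.mean(betas)),
        delta_t=float(np.mean(deltas)),
        m_cs=float(reg_cs.slope),
        c_cs=float(reg_cs.intercept),
        m_sf=float(reg_sf.slope),
        c_sf=float(reg_sf.intercept),
        n_subjects=n,
        stderr=stderr,
    )


def estimate_template(
    cohort,
    test_id: str,
    fits: Mapping[str, FitResult] | None = None,
    seed: int = 0,
) -> CSFTemplate:
    """Estimate the six-parameter normative template for one test.

    Bandwidth and truncation are the means of per-subject full-fit values;
    the two links are ordinary least squares of fitted peak logCS on
    session-averaged letter CS and of fitted log10 peak SF on far acuity.
    On well-formed cohorts ``m_cs > 0`` and ``m_sf < 0``; violations are
    reported in the log, not enforced.
    """
    import logging

    if fits is None:
        fits = fit_cohort(cohort, test_id, seed=seed)
    letter = {rec.id: rec.letter_cs for rec in cohort.subjects if rec.id in fits}
    acuity = {rec.id: rec.far_acuity for rec in cohort.subjects if rec.id in fits}
    template = _template_from_fits(test_id, fits, letter, acuity)
    log = logging.getLogger(__name__)
    if template.m_cs <= 0:
        log.warning("%s: letter-CS link slope m_cs=%.3f is not positive",
                    test_id, template.m_cs)
    if template.m_sf >= 0:
        log.warning("%s: acuity link slope m_sf=%.3f is not negative",
                    test_id, template.m_sf)
    return template


def predict_subject_csf(
    template: CSFTemplate, letter_cs: float, far_acuity: float
) -> CSFParams:
    """Deterministically predict a full CSF from two clinical measurements."""
    if not (np.isfinite(letter_cs) and np.isfinite(far_acuity)):
        raise ValueError("letter_cs and far_acuity must be finite")
    return CSFParams(
        peak_logcs=template.m_cs * letter_cs + template.c_cs,
        peak_sf=10.0 ** (template.m_sf * far_acuity + template.c_sf),
        bandwidth_oct=template.beta_t,
        truncation=template.delta_t,
    )


def loo_evaluate(cohort, test_id: str, seed: int = 0) -> PredictionEvaluation:
    """Leave-one-out evaluation of the zero-free-parameter predictor.

    For each subject, the template is estimated from all other subjects'
    fits, the left-out subject's CSF is predicted from their letter CS and
    far acuity, and the predicted curve is scored against their
    session-averaged logCS at the test's sampled frequencies.  Per-subject
    full-fit and test-retest RMSEs are computed alongside; the summary
    includes a paired t of predicted vs test-retest errors.
    """
    if cohort.n < 4:
        raise ValueError("leave-one-out evaluation requires >= 4 subjects")
    spec = cohort.test_specs[test_id]
    sfs = np.asarray(spec.frequencies, dtype=float)
    fits = fit_cohort(cohort, test_id, seed=seed)
    letter = {rec.id: rec.letter_cs for rec in cohort.subjects}
    acuity = {rec.id: rec.far_acuity for rec in cohort.subjects}

    # Sorting by id makes the folds independent of subject ordering.
    order = sorted(rec.id for rec in cohort.subjects)
    rows = []
    templates: dict[str, CSFTemplate] = {}
    for sid in order:
        rec = cohort.subject(sid)
        rest = {i: fits[i] for i in order if i != sid}
        try:
            template = _template_from_fits(test_id, rest, letter, acuity)
        except ValueError as exc:
            raise ValueError(f"leave-one-out fold for subject {sid}: {exc}") from exc
        templates[sid] = template
        predicted = predict_subject_csf(template, letter[sid], acuity[sid])
        obs = average_sessions(rec).csf_logcs(test_id)
        pred_curve = np.atleast_1d(evaluate_csf(predicted, sfs))
        rmse_pred = rmse(obs, pred_curve)
        fit = fits[sid]
        if rmse_pred < fit.rmse_fitted:
            # the predictor found a better point in the family: refine the
            # fit from there so the fitted RMSE is a true optimum
            refined = fit_csf(
                list(zip(sfs, obs)), seed=seed, extra_starts=[predicted]
            )
            if refined.rmse_fitted < fit.rmse_fitted:
                fits[sid] = fit = refined
        try:
            rmse_tr = rmse_test_retest(rec, test_id)
        except ValueError:
            rmse_tr = float("nan")
        rows.append(
            {
                "subject_id": sid,
                "rmse_predicted": rmse_pred,
                "rmse_fitted": fit.rmse_fitted,
                "rmse_test_retest": rmse_tr,
            }
        )
    per_subject = pd.DataFrame(rows).set_index("subject_id")

    summary: dict[str, float] = {}
    for col in per_subject.columns:
        vals = per_subject[col].dropna()
        summary[f"mean_{col}"] = float(vals.mean()) if len(vals) else float("nan")
        summary[f"sd_{col}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    paired = per_subject.dropna(subset=["rmse_predicted", "rmse_test_retest"])
    if len(paired) >= 2:
        diff = paired["rmse_predicted"] - paired["rmse_test_retest"]
        if float(diff.std(ddof=1)) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(paired["rmse_predicted"], paired["rmse_test_retest"])
        summary["t_predicted_vs_test_retest"] = float(t)
        summary["p_predicted_vs_test_retest"] = float(p)
        summary["df"] = len(paired) - 1
    return PredictionEvaluation(
        test_id=test_id, per_subject=per_subject, summary=summary, templates=templates
    )


_MEASURES = ("far_acuity", "near_acuity", "letter_cs")
_QUANTITIES = (
    "peak_logcs",
    "log_peak_sf",
    "bandwidth_oct",
    "truncation",
    "aulcsf",
    "high_sf_cutoff",
)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    cohort,
    test_ids=None,
    fits_by_test: Mapping[str, Mapping[str, FitResult]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations of fitted CSF quantities with auxiliary measures.

    Correlates far acuity, near acuity and session-averaged letter CS with
    the four fitted parameters (peaks on log scales), the area under the
    log CSF over the test's sampled range, and the high-SF cutoff, per
    test.  Two-sided p-values come from the standard t transform;
    significance stars mark p < 0.05 (*) and p < 0.01 (**).  Zero-variance
    columns yield NaN correlations flagged in the ``note`` column.
    """
    if cohort.n < 4:
        raise ValueError("correlation table requires >= 4 subjects")
    test_ids = list(test_ids or cohort.test_specs)
    rows = []
    for test_id in test_ids:
        spec = cohort.test_specs[test_id]
        fits = (
            fits_by_test[test_id]
            if fits_by_test is not None
            else fit_cohort(cohort, test_id, seed=seed)
        )
        ids = [rec.id for rec in cohort.subjects if rec.id in fits]
        quantities: dict[str, np.ndarray] = {
            "peak_logcs": np.array([fits[i].params.peak_logcs for i in ids]),
            "log_peak_sf": np.array([math.log10(fits[i].params.peak_sf) for i in ids]),
            "bandwidth_oct": np.array([fits[i].params.bandwidth_oct for i in ids]),
            "truncation": np.array([fits[i].params.truncation for i in ids]),
            "aulcsf": np.array(
                [
                    aulcsf(fits[i].params, spec.frequencies[0], spec.frequencies[-1])
                    for i in ids
                ]
            ),
            "high_sf_cutoff": np.array(
                [
                    high_sf_cutoff(fits[i].params)
                    if fits[i].params.peak_logcs >= 0
                    else float("nan")
                    for i in ids
                ]
            ),
        }
        measures = {
            "far_acuity": np.array([cohort.subject(i).far_acuity for i in ids]),
            "near_acuity": np.array([cohort.subject(i).near_acuity for i in ids]),
            "letter_cs": np.array([cohort.subject(i).letter_cs for i in ids]),
        }
        for mname in _MEASURES:
            for qname in _QUANTITIES:
                x, y = measures[mname], quantities[qname]
                ok = np.isfinite(x) & np.isfinite(y)
                note = ""
                if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                    r, p = float("nan"), float("nan")
                    note = "undefined (zero variance or too few finite values)"
                else:
                    r, p = sps.pearsonr(x[ok], y[ok])
                rows.append(
                    {
                        "test_id": test_id,
                        "measure": mname,
                        "quantity": qname,
                        "r": float(r),
                        "p": float(p),
                        "sig": _stars(p) if np.isfinite(p) else "",
                        "n": int(ok.sum()),
                        "note": note,
                    }
                )
    return pd.DataFrame(rows)
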