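"""Nonlinear least-squares fitting of the truncated log parabola.

The fit minimises squared error between measured logCS values and the model
curve over any subset of the four parameters, with the remaining parameters
pinned to supplied values.  Optimisation is bounded (trust-region
reflective via :func:`scipy.optimize.least_squares`) with a data-driven
start plus seeded jittered restarts; the peak spatial frequency is
optimised on the log10 scale.

The truncation depth delta is only identified when a sampled frequency
actually lies on the low-frequency plateau at the solution.  When it does
not, the returned delta is snapped to the smallest value consistent with
the fitted curve (the identifiability floor, or the lower box bound when no
frequency lies below the fitted peak) and the result is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import LOG2, CSFParams, FrequencySample

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "FitResult",
    "rmse",
    "fit_csf",
    "partial_model_analysis",
    "PartialModelResult",
]

PARAM_NAMES = ("peak_logcs", "peak_sf", "bandwidth_oct", "truncation")

#: Default parameter box: covers the plausible clinical range while
#: preventing runaway truncation. peak_sf bounds are in c/deg.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "peak_logcs": (0.0, 3.0),
    "peak_sf": (0.25, 40.0),
    "bandwidth_oct": (0.5, 8.0),
    "truncation": (0.0, 2.0),
}


@dataclass
class FitResult:
    """Outcome of one truncated log-parabola fit."""

    params: CSFParams
    fixed: dict[str, float]
    rmse_fitted: float
    converged: bool
    n_samples: int
    delta_identifiable: bool = True
    n_starts: int = 0

    @property
    def fixed_mask(self) -> tuple[bool, bool, bool, bool]:
        return tuple(name in self.fixed for name in PARAM_NAMES)


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-squared error between two equal-length logCS vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError(
            f"observed and predicted must be equal-length 1-d vectors, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    if obs.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _curve(theta: np.ndarray, logf: np.ndarray) -> np.ndarray:
    """Model curve for theta = (peak_logcs, log10 peak_sf, bandwidth, delta)."""
    p, l0, beta, delta = theta
    w = beta * LOG2 / 2.0
    parab = p - LOG2 * ((logf - l0) / w) ** 2
    return np.where(logf < l0, np.maximum(parab, p - delta), parab)


def _coerce_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    pairs = [
        (float(s[0]), float(s[1])) if not isinstance(s, FrequencySample) else (s.sf, s.log_cs)
        for s in samples
    ]
    sfs = np.array([p[0] for p in pairs])
    obs = np.array([p[1] for p in pairs])
    if np.any(~(sfs > 0)):
        raise ValueError("sample frequencies must be positive")
    if np.any(~np.isfinite(obs)):
        raise ValueError("sample logCS values must be finite")
    if len(np.unique(sfs)) != len(sfs):
        raise ValueError("sample frequencies must be distinct")
    return sfs, obs


def _theta_bounds(bounds: Mapping[str, tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array(
        [
            bounds["peak_logcs"][0],
            math.log10(bounds["peak_sf"][0]),
            bounds["bandwidth_oct"][0],
            bounds["truncation"][0],
        ]
    )
    hi = np.array(
        [
            bounds["peak_logcs"][1],
            math.log10(bounds["peak_sf"][1]),
            bounds["bandwidth_oct"][1],
            bounds["truncation"][1],
        ]
    )
    return lo, hi


def _params_to_theta(params: CSFParams) -> np.ndarray:
    return np.array(
        [params.peak_logcs, params.log_peak_sf, params.bandwidth_oct, params.truncation]
    )


def _theta_to_params(theta: np.ndarray) -> CSFParams:
    return CSFParams(
        peak_logcs=float(theta[0]),
        peak_sf=float(10.0 ** theta[1]),
        bandwidth_oct=float(theta[2]),
        truncation=float(theta[3]),
    )


def fit_csf(
    samples,
    fixed: Mapping[str, float] | None = None,
    init: CSFParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    extra_starts: Iterable[CSFParams] = (),
) -> FitResult:
    """Least-squares fit of the truncated log parabola to logCS samples.

    Parameters
    ----------
    samples
        Sequence of :class:`FrequencySample` (or ``(sf, log_cs)`` pairs) at
        distinct positive frequencies.
    fixed
        Optional mapping from parameter name to a pinned value; those
        parameters are excluded from the optimisation and echoed exactly.
    init
        Optional explicit starting point; otherwise a data-driven start is
        used (peak at the maximum observed logCS and its frequency,
        bandwidth 3 octaves, truncation 0.3).
    bounds
        Optional per-parameter ``(low, high)`` box; defaults to
        :data:`DEFAULT_BOUNDS`.
    n_restarts
        Number of jittered restarts drawn from a generator seeded with
        ``seed``; the best-of-restarts solution wins, ties broken by
        smaller truncation then smaller bandwidth.
    extra_starts
        Additional full parameter sets to use as starting points (e.g.
        solutions of related fits).
    """
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter name in fixed: {name!r}")
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    sfs, obs = _coerce_samples(samples)
    free_idx = [i for i, name in enumerate(PARAM_NAMES) if name not in fixed]
    n_free = len(free_idx)
    if len(sfs) < max(n_free, 1):
        raise ValueError(
            f"need at least {n_free} samples for {n_free} free parameters, got {len(sfs)}"
        )
    logf = np.log10(sfs)
    lo, hi = _theta_bounds(box)

    theta_fixed = np.zeros(4)
    for i, name in enumerate(PARAM_NAMES):
        if name in fixed:
            v = float(fixed[name])
            theta_fixed[i] = math.log10(v) if name == "peak_sf" else v

    def assemble(free_vec: np.ndarray) -> np.ndarray:
        theta = theta_fixed.copy()
        theta[free_idx] = free_vec
        return theta

    def residual(free_vec: np.ndarray) -> np.ndarray:
        return _curve(assemble(free_vec), logf) - obs

    def jacobian(free_vec: np.ndarray) -> np.ndarray:
        theta = assemble(free_vec)
        p, l0, beta, delta = theta
        w = beta * LOG2 / 2.0
        rel = (logf - l0) / w
        parab = p - LOG2 * rel * rel
        on_plateau = (logf < l0) & (parab < p - delta)
        J = np.empty((logf.size, 4))
        J[:, 0] = 1.0  # d/d peak_logcs (both branches)
        J[:, 1] = np.where(on_plateau, 0.0, 2.0 * LOG2 * rel / w)
        J[:, 2] = np.where(on_plateau, 0.0, 2.0 * LOG2 * rel * rel / beta)
        J[:, 3] = np.where(on_plateau, -1.0, 0.0)
        return J[:, free_idx]

    if n_free == 0:
        pred = _curve(theta_fixed, logf)
        return FitResult(
            params=_theta_to_params(theta_fixed),
            fixed=fixed,
            rmse_fitted=rmse(obs, pred),
            converged=True,
            n_samples=len(sfs),
        )

    # Starting points: data-driven (or user-supplied), jittered restarts,
    # then any caller-provided extra starts.
    if init is not None:
        theta0 = _params_to_theta(init)
    else:
        k = int(np.argmax(obs))
        theta0 = np.array([obs[k], logf[k], 3.0, 0.3])
    starts = [theta0]
    rng = np.random.default_rng(seed)
    jitter_scale = np.array([0.3, 0.25, 0.8, 0.2])
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(0.0, 1.0, 4) * jitter_scale)
    for p in extra_starts:
        starts.append(_params_to_theta(p))

    best = None
    any_success = False
    for theta_start in starts:
        x0 = np.clip(theta_start[free_idx], lo[free_idx] + 1e-12, hi[free_idx] - 1e-12)
        try:
            res = least_squares(
                residual,
                x0,
                jac=jacobian,
                bounds=(lo[free_idx], hi[free_idx]),
                method="trf",
                x_scale=1.0,
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-12,
                max_nfev=200,
            )
        except Exception:
            continue
        any_success = any_success or res.success
        theta = assemble(res.x)
        cost = float(res.cost)
        key = (cost, theta[3], theta[2])
        if best is None or _better(key, best[0]):
            best = (key, theta, cost)
    if best is None:
        raise RuntimeError("all fit starts failed")
    _, theta_best, cost = best
    pred = _curve(theta_best, logf)
    fit_rmse = rmse(obs, pred)

    # Truncation identifiability: delta only matters where the plateau
    # covers a sample.  Snap unidentified deltas down to the smallest value
    # consistent with the fitted curve and flag the result.
    delta_identifiable = True
    if "truncation" not in fixed:
        p_hat, l0_hat, beta_hat, delta_hat = theta_best
        w = beta_hat * LOG2 / 2.0
        below = logf < l0_hat
        if not np.any(below):
            theta_best[3] = box["truncation"][0]
            delta_identifiable = False
        else:
            parab_below = p_hat - LOG2 * ((logf[below] - l0_hat) / w) ** 2
            floor = max(box["truncation"][0], p_hat - float(np.min(parab_below)))
            if delta_hat >= floor - 1e-9:
                # cost is flat for all delta >= floor (plateau at or below
                # the parabola at every sample): report the floor itself
                theta_best[3] = min(max(floor, box["truncation"][0]),
                                    box["truncation"][1])
                delta_identifiable = False

    return FitResult(
        params=_theta_to_params(theta_best),
        fixed=fixed,
        rmse_fitted=fit_rmse,
        converged=bool(any_success),
        n_samples=len(sfs),
        delta_identifiable=delta_identifiable,
        n_starts=len(starts),
    )


def _better(key_a, key_b, tol: float = 1e-12) -> bool:
    """Cost comparison with tie-breaks on smaller delta then bandwidth."""
    ca, da, ba = key_a
    cb, db, bb = key_b
    if ca < cb - tol:
        return True
    if ca > cb + tol:
        return False
    return (da, ba) < (db, bb)


# ---------------------------------------------------------------------------
# Partial-model analysis: which parameters carry individual differences?
# ---------------------------------------------------------------------------

PARTIAL_CONDITIONS = ("none", "peak_logcs", "peak_sf", "bandwidth_oct", "truncation", "all")


@dataclass
class PartialModelResult:
    """Per-subject RMSE for full, partial-fixed, and fully pinned fits.

    ``per_subject`` has one row per subject and one column per condition;
    ``summary`` carries the group mean and standard error per condition;
    ``comparisons`` holds paired t statistics of each condition against the
    full model ("none").
    """

    per_subject: "pandas.DataFrame"  # noqa: F821 - imported lazily
    summary: "pandas.DataFrame"  # noqa: F821
    comparisons: "pandas.DataFrame"  # noqa: F821
    group_means: dict[str, float] = field(default_factory=dict)


def partial_model_analysis(cohort, test_id: str, seed: int = 0) -> PartialModelResult:
    """Refit each subject with named parameters pinned to the group mean.

    The group means come from full four-parameter fits to session-averaged
    data.  Condition ``"none"`` is the full fit (lower bound on RMSE),
    ``"all"`` pins every parameter (zero free parameters, upper bound), and
    each single-parameter condition pins just that parameter.
    """
    import pandas as pd
    from scipy import stats as sps

    from .repeatability import average_sessions

    if len(cohort.subjects) < 2:
        raise ValueError("partial-model analysis requires at least 2 subjects")
    spec = cohort.test_specs[test_id]
    sfs = np.asarray(spec.frequencies, dtype=float)

    averaged = [average_sessions(s) for s in cohort.subjects]
    full_fits: dict[str, FitResult] = {}
    for rec in averaged:
        obs = rec.csf_logcs(test_id)
        full_fits[rec.id] = fit_csf(list(zip(sfs, obs)), seed=seed)

    group_means = {
        name: float(np.mean([getattr(f.params, name) for f in full_fits.values()]))
        for name in PARAM_NAMES
    }

    rows: dict[str, dict[str, float]] = {c: {} for c in PARTIAL_CONDITIONS}
    partial_solutions: dict[str, list[CSFParams]] = {rec.id: [] for rec in averaged}
    for condition in PARTIAL_CONDITIONS:
        if condition == "none":
            continue
        fixed = (
            group_means
            if condition == "all"
            else {condition: group_means[condition]}
        )
        for rec in averaged:
            obs = rec.csf_logcs(test_id)
            extra = [full_fits[rec.id].params]
            if condition != "all":
                # start the free parameters from the group-mean point too
                extra.append(CSFParams(**group_means))
            fit = fit_csf(
                list(zip(sfs, obs)), fixed=fixed, seed=seed, extra_starts=extra
            )
            rows[condition][rec.id] = fit.rmse_fitted
            if condition != "all":
                partial_solutions[rec.id].append(fit.params)

    # Refine the full fits with the partial solutions as extra starts so the
    # nested-model ordering is not an artefact of local optima.
    for rec in averaged:
        obs = rec.csf_logcs(test_id)
        refined = fit_csf(
            list(zip(sfs, obs)), seed=seed, extra_starts=partial_solutions[rec.id]
        )
        if refined.rmse_fitted < full_fits[rec.id].rmse_fitted:
            full_fits[rec.id] = refined
        rows["none"][rec.id] = full_fits[rec.id].rmse_fitted

    per_subject = pd.DataFrame(rows)[list(PARTIAL_CONDITIONS)]
    summary = pd.DataFrame(
        {
            "mean_rmse": per_subject.mean(),
            "sem_rmse": per_subject.sem(),
            "n": per_subject.count(),
        }
    )
    comp_rows = []
    for condition in PARTIAL_CONDITIONS:
        if condition == "none":
            continue
        diff = per_subject[condition] - per_subject["none"]
        if float(diff.std(ddof=1)) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(per_subject[condition], per_subject["none"])
        comp_rows.append(
            {"condition": condition, "t_vs_none": float(t), "p": float(p),
             "df": len(per_subject) - 1}
        )
    comparisons = pd.DataFrame(comp_rows).set_index("condition")
    return PartialModelResult(
        per_subject=per_subject,
        summary=summary,
        comparisons=comparisons,
        group_means=group_means,
    )
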