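# Methods

## The model

csfkit models the contrast sensitivity function (CSF) — threshold contrast
sensitivity as a function of spatial frequency — with the four-parameter
truncated log parabola. Writing `l = log10(f)` and `l0 = log10(peak_sf)`,
the untruncated curve is a downward parabola in log-log coordinates,

```
S'(f) = peak_logcs − log10(2) · ((l − l0) / w)²,   w = bandwidth_oct · log10(2) / 2,
```

so that the curve drops by exactly `log10(2)` (half-maximum sensitivity) at
one half-bandwidth either side of the peak. Below the peak frequency the
curve is not allowed to fall under an asymmetric plateau sitting
`truncation` (δ) logCS below the peak:

```
S(f) = S'(f)                          f ≥ peak_sf
S(f) = max(S'(f), peak_logcs − δ)     f < peak_sf
```

Parameters, units, and default fitting box:

| parameter       | meaning                          | units   | box        |
|-----------------|----------------------------------|---------|------------|
| `peak_logcs`    | log10 sensitivity at the peak    | logCS   | [0, 3]     |
| `peak_sf`       | frequency of the peak            | c/deg   | [0.25, 40] |
| `bandwidth_oct` | full width at half max sensitivity | octaves | [0.5, 8] |
| `truncation`    | plateau depth below the peak     | logCS   | [0, 2]     |

Bandwidth is stored in octaves (the literature convention for this
function; it makes the half-height identity exact). Sensitivity is carried
in log10 units everywhere; decimal sensitivity is available via helpers.

Two summary statistics derive from the parameters. The AULCSF integrates
`max(S, 0)` over log10 frequency between two bounds (default: the test's
own sampled range); it is computed in closed form from the piecewise
plateau/parabola structure, with the sub-zero portion clipped (area of the
*visible* contrast range). The high-SF cutoff is the closed-form frequency
above the peak where the parabola crosses 0 logCS (threshold = 100%
contrast); a zero-height curve returns the peak frequency by convention,
and a negative peak raises.

## Fitting

`fit_csf` minimises squared error of `S(f)` against measured logCS values
with bounded trust-region least squares (`scipy.optimize.least_squares`,
analytic Jacobian, peak frequency optimised on the log10 scale). Any subset
of the four parameters can be pinned to supplied values and is echoed
exactly. Starts are data-driven (peak at the maximum observed logCS and its
frequency, bandwidth 3 octaves, δ 0.3) plus four seeded jittered restarts;
best-of-restarts wins, with cost ties broken toward smaller δ then smaller
bandwidth. Callers may inject extra starting points; the partial-model and
leave-one-out routines use this to restart related fits from each other's
solutions, which can only improve the least-squares optimum and keeps the
nested-model and unity-line orderings from being artefacts of local optima.

**Truncation identifiability.** δ only influences the objective when a
sampled frequency lies on the plateau. When no sampled frequency falls
below the fitted peak at all, δ is reported at the lower box bound and the
result is flagged; when frequencies lie below the peak but the plateau sits
at or below the parabola at every one of them, the cost is flat for all
δ ≥ the identifiability floor (`p̂ − min S'(f)` over sampled `f` below the
peak), and the floor itself is reported, flagged. Template estimation
averages δ only over subjects whose δ was identified (falling back to all
subjects when none are), because floor-snapped values would bias the
template truncation downward; this mattered in practice for the chart-test
configuration, whose four sampled frequencies start at 3 c/deg.

With four sampled frequencies and four free parameters (the chart test)
the fit is exactly identified; the convergence flag carries the warning.

## Repeatability

Bland–Altman agreement between two sessions: differences are oriented
session 2 − session 1, the coefficient of repeatability is
`COR = 1.96 · SD(d)` with the sample (n−1) standard deviation, and the bias
is `mean(d)`. Incomplete pairs are dropped and counted. Because the two
sessions agree well under the intended operating conditions, all downstream
analyses use session-averaged data (element-wise mean per frequency, and of
the two letter-CS values; acuity is measured once and passes through). A
subject's per-test retest error is the RMSE between their two session
vectors — the natural per-subject noise benchmark for predictions.

## The normative template and zero-free-parameter prediction

The predictive model asserts that individuals differ mainly by vertical
(peak logCS) and horizontal (log peak SF) shifts of a standard-shaped,
test-specific CSF. Six numbers summarise a cohort: the group means of
fitted bandwidth and truncation (β_T, δ_T), and two ordinary least-squares
links — fitted peak logCS on measured letter CS (slope m_cs, intercept
c_cs) and fitted log10 peak SF on far acuity in logMAR (m_sf, c_sf; the
slope is expected negative since better acuity means lower logMAR). Peak SF
is regressed and predicted on the log10 scale, consistent with the
template-shift picture operating on log axes. Far (not near) acuity feeds
the frequency link, and the letter-CS input is the session-averaged value.
Template estimation uses full four-parameter per-subject fits as the
regression targets.

Prediction is then deterministic — zero free parameters per subject:
`peak_logcs = m_cs·letterCS + c_cs`, `peak_sf = 10^(m_sf·acuity + c_sf)`,
bandwidth β_T, truncation δ_T.

Evaluation is leave-one-out: each subject's template is estimated from the
other n−1 subjects, the predicted curve is evaluated at the test's sampled
frequencies, and `RMSE_predicted` is compared per subject against
`RMSE_fitted` (the four-parameter least-squares optimum — a lower bound
within the model family, hence every point sits on or above the unity
line) and `RMSE_test-retest` (instrument repeatability — the practical
target: a predictor that matches it extracts essentially everything the
test can reliably measure). The group summary includes the paired t of
predicted vs test-retest errors. Folds are processed in sorted-id order, so
results are independent of subject ordering.

Correlation tables report Pearson r (with the standard two-sided t-based
p-value and 0.05/0.01 stars) between the auxiliary measures (far/near
acuity, letter CS) and the fitted parameters (peaks on log scales), AULCSF
and high-SF cutoff. No multiple-testing correction is applied anywhere;
every p-value in the reports is raw. This is stated in the report itself.

## Synthetic cohorts

The raw clinical data the framework targets are not distributable, so the
package ships a seeded generator that emulates their statistical structure;
every subject draws from a substream keyed by (seed, subject index), making
cohorts order-independent and bit-reproducible.

Per subject: far acuity ~ Normal(−0.05, 0.12) truncated to [−0.3, 0.34]
logMAR; near acuity = far + Normal(0, 0.05); true letter CS ~ Normal(1.57,
0.25) truncated to [0.5, 2.25] logCS, with two measured sessions adding
Normal noise (SD 0.14) and a +0.01 retest bias; age/disease follow a
two-component mixture (healthy 36 ± 10.5 years, ~2/3 of subjects; disease
58 ± 16.6). Ground-truth CSF parameters follow the template structure:
`peak_logcs = m_cs·letterCS + c_cs + N(0, σ_cs)`, `log10 peak_sf =
m_sf·acuity + c_sf + N(0, σ_sf)`, bandwidth and truncation Normal around
β_T, δ_T (truncated to valid ranges). Generator defaults: m_cs = 0.8,
c_cs = 0.7, m_sf = −1.0, c_sf = 0.6, β_T = 3, δ_T = 0.4, all σ = 0.1.
These are configuration choices, not empirical estimates.

Three instrument styles are emulated at the *output* level (no
trial-by-trial psychophysics — no staircases, adaptive placement, lapses):

- **Sine-grating test**: five frequencies (1.5–18 c/deg), continuous logCS,
  session noise SD 0.18.
- **Chart test**: four frequencies (3–18 c/deg), eight discrete contrast
  levels per frequency, session noise SD 0.12. The vendor's score→logCS
  table is proprietary, so the default grid is eight log-spaced contrast
  levels from 0.5% upward spanning 0.9 logCS, user-overridable; what
  matters is preserving the quantisation *mechanism*. Values snap to the
  nearest level, ties toward lower sensitivity, flooring at the lowest
  level.
- **Adaptive test**: five frequencies, session noise SD 0.08, and
  (toggleable) refit smoothing — the emitted session is the model curve
  re-fitted to the noisy samples, mimicking instruments whose report is
  itself a constrained parametric estimate, which smooths across
  frequencies.

All outputs are clipped to the displayable range [0, log10(1/0.005) ≈ 2.30]
logCS implied by the 0.5% minimum contrast. The session noise SDs were set
by inverting COR = 1.96·√2·σ against repeatability levels published for
these instrument classes (roughly 0.5 / 0.33 / 0.22 logCS), preserving the
characteristic ordering sine > chart > adaptive; the retest bias of +0.05
logCS emulates a small practice effect.

Two named configurations support the validation studies. The zero-noise
configuration switches every noise source off and adjusts the link
intercepts (c_cs = 0.35, c_sf = 1.0) so that generated curves stay inside
the displayable range and the plateau is expressed at 1.5 c/deg for every
subject — in that regime the model is exactly identifiable end-to-end and
leave-one-out predictions reproduce the generative curves to numerical
precision. The matched-noise configuration (σ_cs = 0.17, σ_sf = 0.12,
sine test only) was derived from the error-budget identity
`E[mean e²] ≈ σ²/2 + V_pred` so that leave-one-out prediction RMSE lands in
the same range as test–retest RMSE (~0.23 vs ~0.25 logCS) — the operating
regime the predictive framework targets, where the paired t of the two
error distributions is small.

## What the synthetic data do and do not show

The generator reproduces the *assumed* statistical structure: linear links
on log scales, Gaussian measurement noise, quantisation, smoothing,
range limits. Real cohorts additionally contain mid-frequency notches,
non-Gaussian and frequency-correlated errors, disease-specific shape
changes, and link nonlinearity — none of which are emulated. Passing tests
therefore demonstrate that the estimators are correct and well-calibrated
*under the model's assumptions*, not that the model is adequate for any
particular clinical population.

## Study sizes and numerical choices

Validation studies use desk-scale sizes chosen once: 100-subject cohorts
for the partial-model nesting study, 43 subjects (the study-scale cohort
size) for leave-one-out and repeatability studies, 100 replicates for
template recovery, 200 replicates for COR calibration. The
template-recovery study generates from a deliberately well-conditioned
template (m_cs = 0.6, c_cs = 0.55, m_sf = −0.6, c_sf = 0.8, β_T = 3,
δ_T = 0.3): peaks interior to the sampled range and curves clear of the
instrument floor/ceiling. Outside that regime the nonlinear per-subject
fits acquire a systematic bandwidth/truncation bias (apex extrapolation and
clipping), which is a property of 5-point maximum-likelihood fitting, not
of the template estimator; the recovery claim is about the latter.

Solver tolerances are 1e−10 (xtol/ftol) with an analytic Jacobian; the
refit-smoothing inside the adaptive-test emulation uses a single
data-driven start since it only needs a smooth interpolant. AULCSF is exact
closed form; tests cross-check it against adaptive quadrature at 1e−6 and
the cutoff against bisection at 1e−9. Degenerate inputs (empty grids,
non-positive frequencies, too few samples or subjects, zero-variance
predictors) raise with the offending item named.

## Known limitations

- δ and, to a lesser degree, bandwidth are weakly identified from 4–5
  frequencies; per-subject estimates of these are noisy by nature, which is
  precisely why the template treats them as group constants.
- The unity-line guarantee is enforced up to solver tolerance (1e−6) by
  restarting fits from the predicted parameters when the prediction wins.
- The chart-test grid is a stand-in for a proprietary translation table;
  absolute chart logCS levels should not be compared against real chart
  scores without supplying the instrument's own grid.
- Group-comparison statistics (one-way ANOVA across tests, paired t tests)
  are routine textbook formulas included for report parity.
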