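# Methods

## Model and procedure

The package treats one scalar estimand per participant. Stage one produces,
for each participant $i$ of a cohort of $k$, a maximum-likelihood estimate
$y_i$ and an error variance $\sigma_i^2$ from a (possibly truncated)
time-series trial. Stage two shrinks the cohort jointly:

- grand mean $\bar y = \tfrac1k \sum y_i$;
- pooled squared standard error $\overline{SE}^2 = \tfrac1k \sum \sigma_i^2$
  (the plain mean — inverse-variance weighting is deliberately not used, so
  a cohort with unequal precisions is pooled the simple way);
- shrinkage factor
  $c = 1 - \overline{SE}^2 (k-3) / \sum_i (y_i-\bar y)^2$;
- James-Stein estimates $z_i = \bar y + c\,(y_i - \bar y)$.

The positive-part rule ($c < 0 \mapsto 0$) is the default because the
positive-part estimator dominates the raw one; raw mode is retained for
exact reproduction of the formula. The $(k-3)$ numerator is specific to
shrinking toward the estimated grand mean (one degree of freedom is spent on
$\bar y$); $k \ge 4$ is therefore enforced. Shrinkage is affine about
$\bar y$, which yields three invariants the tests exercise: the mean of the
$z_i$ equals $\bar y$ exactly, $|z_i - \bar y| \le |y_i - \bar y|$ for
$0 \le c \le 1$, and ranking is preserved whenever $c > 0$.

Accuracy is summed squared error against per-participant reference values
$x_i$, compared between MLE and JSE, with two paired two-sided t-tests: one
on the per-participant squared errors of MLE vs JSE (absolute and signed
error variants are available — which error the pairing should use is a
genuinely open choice), one on $x_i$ vs $y_i$ as a bias check. Identical
pairs are reported as $p = 1$ rather than NaN, since "no difference" is the
correct reading. When $\mathrm{SSE}_\mathrm{MLE} = 0$ the percent reduction
is 0 if the JSE is also perfect and $-\infty$ otherwise (a perfect MLE can
only be hurt).

## The three estimators

**Foot-placement gain.** Steps are (midstance pelvis state $P$ = sideways
position, sideways velocity, forward velocity; next foot position $S$ =
sideways, forward). Both sides are centered by the means of the analyzed
window and the 2×3 gain matrix solved by OLS per output row, no intercept.
Coefficient variances use $s^2\,\mathrm{diag}((X^TX)^{-1})$ with
$s^2 = \mathrm{RSS}/(n-3)$ — three regressors, no intercept after
centering, hence $n-3$ residual degrees of freedom (the df convention is a
package choice; with $n \ge 15$ windows it is numerically minor). The shrunk
element defaults to row "sideways foot", column "sideways pelvis velocity"
(units: s) and is configurable. A minimum of 7 steps is required for the 6
gains to be identifiable with at least one residual df per row.

**Steady-state metabolic rate.** Gas fluxes (mL·s⁻¹·kg⁻¹) convert to power
via $\dot E = 16.58\,\dot V_{O_2} + 4.51\,\dot V_{CO_2}$ W/kg. The
transient $\dot E = a_0 + a_1 e^{-t/\tau}$ is fitted by bounded
Levenberg–Marquardt/TRF least squares; initialization $a_0$ = mean of the
last third of the window, $a_1$ = first sample − $a_0$, $\tau$ = span/3;
bounds $\tau \in (0.1\,\mathrm{s}, 10 \times \mathrm{span})$. A perfectly
flat window short-circuits to the sample mean ($\tau$ is unidentifiable
there); optimizer failure returns the initial iterate flagged
non-converged. $\sigma_i^2$ is the variance of $a_0$ over case-resampled
refits (breaths resampled with replacement, re-sorted; B configurable,
default 200 inside sweeps, 1000 standalone). Refits whose fitted $\tau$
exceeds the window span never see their plateau, so their $a_0$ is an
unconstrained extrapolation with arbitrarily heavy tails; they are censored
from the variance provided at least 30% of refits resolve a plateau
in-window (otherwise all converged refits count and the variance is
honestly large). Without this censoring a single unstable participant can
inflate $\overline{SE}^2$ — and since the pooling is a plain mean, collapse
$c$ for the entire cohort. More than 20% outright optimizer failures is an
error advising a longer window.

**Resting metabolic rate.** The estimate is the mean power over the first
$n$ breaths. One variance is shared by the whole cohort: each participant's
deviations from their own window mean are pooled, and the squared standard
error of an $n$-sample mean is the variance over B draws of the mean of $n$
deviations resampled from the pool. On i.i.d. deviations this converges to
$s^2(1-1/n)/n \approx s^2/n$.

**Truncation convention.** All estimators use the *first* $n$ records:
metabolic transients live at the start of a trial, so any other window
changes the estimand; window means (the centering $P^*, S^*$) are
recomputed per truncation.

## Duration sweeps

For each $n$ in a grid, the cohort is estimated, shrunk, and scored. The
reference is the estimate at the full trial length (truth-proxy mode — what
a practitioner can actually compute) or, on synthetic cohorts, the
generative truth (recovery mode). Default grids: 15–90 steps by 5 against
100; 15–51 breaths by 3 against 54; 10–34 breaths by 3 against 40. The
JSE's SSE-vs-$n$ curve is summarized by $a\,e^{-bn}$ via OLS on
$\log \mathrm{SSE}$ (non-positive SSEs are dropped with a warning; fewer
than 3 survivors is an error). Bootstrap seeds derive deterministically
from a root seed per (grid value, participant, replicate) via
`numpy.random.SeedSequence`, so sweeps are reproducible while draws stay
independent.

Truth-proxy mode has a known artifact, deliberately preserved: the proxy
itself carries sampling error, and the short window is nested inside the
truth window, so their errors correlate. As $n$ approaches the truth size
the apparent percent reduction becomes unreliable and can go negative. The
tests demonstrate this on the kinematic cohort; recovery mode shows the
artifact-free picture.

## Synthetic cohorts

The generators mirror exactly the structure the estimators assume — which
is what makes them fair for validating the machinery and quantifying
expected behavior, and silent about anything the model omits (drift,
autocorrelated breath noise, non-Gaussian or clustered populations,
gait-cycle dynamics beyond the linear step-to-step map). Defaults, chosen
once to echo the scale of treadmill / circle-walking / sitting studies:

| parameter | kinematic | walking metabolic | resting |
|---|---|---|---|
| participants $k$ | 8 | 11 | 27 |
| records | 100 steps | ~60 breaths / 390 s | ~46 breaths / 390 s |
| target mean ± between-SD | 0.30 ± 0.06 s | 5.0 ± 0.5 W/kg | 1.5 ± 0.15 W/kg |
| within noise | 8 mm/step | 0.25 W/kg | 0.10 W/kg |
| other | pelvis-state SDs 10 mm, 50 mm/s, 40 mm/s | $a_1$ −3.5 ± 0.5 W/kg, $\tau$ 30 ± 8 s, breaths 6.5 ± 1.2 s | breaths 8.5 ± 1.5 s |

Rationale: sideways foot-placement gains near 0.3 s and millimeter-scale
placement residuals are typical of treadmill walking; walking at ~1.3 m/s
costs roughly 5 W/kg against a ~1.5 W/kg resting baseline, with exercise
transients of a half-minute; resting data get low within-participant noise
relative to between-participant spread, so the resting cohort exhibits the
"minimal shrinkage, minimal benefit" regime while the kinematic cohort
shows the strong-benefit regime. Breath intervals were set so a 390 s trial
essentially always reaches the 54 / 40 breath truth sizes. Gas pairs are
back-computed from each (noisy, floored at zero) power sample at a fixed
respiratory exchange ratio of 0.85, so the Brockway conversion is exercised
as an exact inverse-then-forward identity. Non-positive draws of $\tau$ and
of breath intervals are redrawn. Everything is deterministic given the spec
seed.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq` with an explicit rank check that names a
  constant pelvis-state column; collinearity without a constant column is
  reported as such.
- Zero spread across participants with positive pooled variance leaves the
  raw factor undefined ($-\infty$ in the limit): raw mode raises,
  positive-part mode warns and collapses fully to the grand mean.
- `stein_dominance_check` fixes the true means across replicates, so the
  per-participant bias/variance decomposition across replicates satisfies
  MSE = bias² + variance as an exact identity (checked numerically), and
  the MLE's mean SSE is the analytic $k\sigma^2$.
- Problem sizes in the test and acceptance runs: 2000-replicate dominance
  grid over $k \in \{4,8,16,27\}$ × spread/σ ∈ {0, 0.5, 1, 2};
  500-replicate transient-fit consistency; 200-replicate sweep recovery
  studies; pooled bootstrap B = 2000; walking-metabolic bootstrap B =
  100–300 inside sweeps (each draw is a nonlinear refit, and the shrinkage
  uses only the cohort mean of the variances, which converges much faster
  than an individual quantile).

## Limitations

- The exponential-transient bootstrap is case-resampling by default;
  residual resampling (often more stable for fixed design points) is not
  implemented.
- The pooled resting variance assumes exchangeable within-participant noise
  across the cohort; participants with genuinely different noise levels are
  averaged over.
- Shrinkage assumes one Gaussian cluster of participant means. Cohorts
  mixing distinct subpopulations should be clustered first; no such
  clustering is provided.
- The external-deposit adapter is column-mapping-driven and validated only
  against this package's own export dialect; an arbitrary deposit needs a
  hand-written map.
- Passing tests on the synthetic cohorts certify the estimation and
  shrinkage machinery and its expected behavior *under the generative
  model*; they do not certify effect sizes on real data, whose noise
  structure is richer.
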