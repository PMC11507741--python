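# steinshrink

Shrinkage estimation for human movement and metabolic studies: when the same
quantity is estimated for every participant in a cohort from short or noisy
trials, the James-Stein estimator (JSE) pools information across participants
to cut the cohort's total squared estimation error — letting shorter trials
deliver the accuracy of longer ones. This matters wherever trial duration is
expensive or physically limited: elderly or impaired populations, prosthesis
and exoskeleton fitting, human-in-the-loop optimization.

## The estimator

Given per-participant maximum-likelihood estimates $y_i$ ($i = 1 \dots k$)
with error variances $\sigma_i^2$, each James-Stein estimate shrinks its MLE
toward the cohort grand mean $\bar{y} = \sum_i y_i / k$:

$$z_i = \bar{y} + c\,(y_i - \bar{y}), \qquad
  c = 1 - \frac{\overline{SE}^2\,(k-3)}{\sum_i (y_i - \bar{y})^2},$$

with $\overline{SE}^2$ the mean of the individual error variances. $c = 1$
leaves the MLEs untouched; $c = 0$ collapses everyone onto the grand mean; a
negative $c$ is clamped to zero (the positive-part rule, which dominates the
raw estimator). Accuracy is scored by summed squared error from
per-participant truths $x_i$:
$\mathrm{SSE} = \sum_i (x_i - \hat{x}_i)^2$, compared between MLE and JSE.
For $k \ge 4$ the positive-part JSE's expected SSE never exceeds the MLE's —
it trades a small bias for a large variance reduction.

Three estimation problems are built in, each producing the $(y_i,
\sigma_i^2)$ pairs the shrinkage consumes:

* **Foot-placement control** during treadmill walking: OLS regression of the
  next stance-foot position on the midstance pelvis state (sideways
  position, sideways velocity, forward velocity), both mean-centered, giving
  a 2×3 gain matrix $J$; the shrunk scalar is
  $\partial X_\mathrm{foot} / \partial \dot{X}_\mathrm{pelvis}$, with
  $\sigma_i^2$ from the regression's coefficient variance.
* **Walking metabolic rate**: breath-by-breath gas fluxes are converted to
  metabolic power by the Brockway equation
  $\dot{E} = 16.58\,\dot{V}_{O_2} + 4.51\,\dot{V}_{CO_2}$ (W/kg from
  mL·s⁻¹·kg⁻¹), and the steady state $a_0$ of the transient
  $\dot{E} = a_0 + a_1 e^{-t/\tau}$ is fitted by nonlinear least squares;
  $\sigma_i^2$ from a case-resampling bootstrap.
* **Resting metabolic rate**: the mean power over a window of breaths, with
  a single cohort-wide $\sigma^2$ from a pooled-deviation bootstrap.

A truncation sweep recomputes everything from the first $n$ records for a
grid of $n$, scores against the full-duration estimate (the practical
stand-in for the unknowable truth), and fits the decay
$\mathrm{SSE}(n) = a\,e^{-b n}$. Synthetic cohort generators with known
ground truth make every stage testable end to end.

## Worked example

```python
import steinshrink as ss

co = ss.CohortEstimates([
    ss.PointEstimate(f"P{i}", float(i), 1.0, 10, "resting_mean")
    for i in (1, 2, 3, 4, 5)])
res = ss.compute_shrinkage(co)
print(res.raw_c, res.shrunk_values)
```

prints `0.8 [1.4 2.2 3. 3.8 4.6]`: with unit error variances and spread
$\sum (y_i-\bar y)^2 = 10$, the factor is $1 - 1\cdot(5-3)/10 = 0.8$, and
each estimate moves 20% of the way to the mean of 3.

The analysis pipeline runs as numbered scripts (each writes tables under
`results/`):

```bash
python analysis/01_simulate_cohorts.py     # three synthetic cohorts + truth
python analysis/02_participant_estimates.py
python analysis/03_shrinkage_snapshots.py
python analysis/04_duration_sweeps.py
python analysis/05_stein_dominance.py
```

`03` prints, for the default seed, the short-window snapshots — e.g.

```
kinematic: c=0.895, SSE 0.0095 -> 0.008515 (+10.4%), p=0.579
resting:   c=0.980, SSE 0.008051 -> 0.007377 (+8.4%), p=0.195
```

meaning the 25-step foot-placement estimates were shrunk ~10% toward their
mean and ended 10.4% closer (in total squared error) to the 100-step
estimates; a single cohort draw is noisy, and the walking-metabolic snapshot
can come out negative on one draw. `04` shows the systematic picture: the
shrinkage factor rises toward 1 as windows lengthen (e.g. kinematic
0.829 → 0.965 from 15 to 90 steps) while the JSE's SSE decays roughly
exponentially in window length. `05` verifies dominance by Monte Carlo: at
$k=16$ equal true means and unit noise, mean SSE drops from 15.7 (the
analytic $k\sigma^2 = 16$) to 2.1.

The same stages are available as a CLI (`steinshrink simulate / estimate /
shrink / sweep / reproduce`); `reproduce` adapts an externally deposited
dataset through a YAML column map and recomputes a snapshot on it.

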