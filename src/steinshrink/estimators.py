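"""Per-participant maximum-likelihood estimates and their error variances.

Three estimation problems, one per dataset kind:

* **Foot-placement control** — ordinary least squares of the next stance-foot
  position on the midstance pelvis state, both mean-centered, giving a 2x3
  gain (Jacobian) matrix.  The estimand shrunk downstream is a single element
  of that matrix, by default the sensitivity of sideways foot placement to
  sideways pelvis velocity.
* **Walking metabolic rate** — nonlinear fit of an exponential transient
  ``Edot = a0 + a1*exp(-t/tau)`` to breath-by-breath metabolic power; the
  steady-state asymptote ``a0`` is the estimand, with a case-resampling
  bootstrap giving its error variance.
* **Resting metabolic rate** — the sample mean of metabolic power over a
  window of breaths, with a single cohort-wide error variance obtained by
  pooling every participant's deviations from their own window mean and
  bootstrapping the mean of ``n`` resampled deviations.

All estimators accept a truncation count ``n`` and always use the FIRST ``n``
records of a trial: transients live at the start of a trial, so any other
window would change the estimand.  Window means are recomputed per truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "StepRecord",
    "KinematicTrial",
    "JacobianFit",
    "BreathRecord",
    "MetabolicTrial",
    "TransientFit",
    "PointEstimate",
    "BROCKWAY_O2",
    "BROCKWAY_CO2",
    "brockway_rate",
    "fit_foot_placement_jacobian",
    "extract_gain_element",
    "fit_exponential_transient",
    "steady_state_estimate",
    "resting_mean_estimate",
]

# Brockway-equation coefficients: W/kg per (mL s^-1 kg^-1) of O2 / CO2 flux.
BROCKWAY_O2 = 16.58
BROCKWAY_CO2 = 4.51

#: names of the pelvis-state regressors, in column order
PELVIS_STATE_COLUMNS = ("x_pelvis", "vx_pelvis", "vy_pelvis")
#: names of the foot-placement outputs, in row order
FOOT_COLUMNS = ("x_foot", "y_foot")


@dataclass(frozen=True)
class StepRecord:
    """One walking step: midstance pelvis state and the next foot placement.

    Units: positions in m, velocities in m/s.
    """

    x_pelvis: float
    vx_pelvis: float
    vy_pelvis: float
    x_foot: float
    y_foot: float


@dataclass
class KinematicTrial:
    """Ordered step-level data for one participant.

    Stored as column arrays (one entry per step, in temporal order); use
    :meth:`from_records` / :meth:`records` for the row-wise view.
    """

    participant_id: str
    x_pelvis: np.ndarray
    vx_pelvis: np.ndarray
    vy_pelvis: np.ndarray
    x_foot: np.ndarray
    y_foot: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, c), dtype=float) for c in
                  PELVIS_STATE_COLUMNS + FOOT_COLUMNS]
        n = {a.shape for a in arrays}
        if len(n) != 1 or arrays[0].ndim != 1:
            raise ValueError("all step columns must be 1-D and equally long")
        for name, a in zip(PELVIS_STATE_COLUMNS + FOOT_COLUMNS, arrays):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite value in column {name!r}")
            setattr(self, name, a)

    @property
    def n_steps(self) -> int:
        return self.x_pelvis.size

    def pelvis_state(self) -> np.ndarray:
        """(n_steps, 3) midstance pelvis-state matrix P."""
        return np.column_stack([self.x_pelvis, self.vx_pelvis, self.vy_pelvis])

    def foot_placement(self) -> np.ndarray:
        """(n_steps, 2) next-foot-position matrix S."""
        return np.column_stack([self.x_foot, self.y_foot])

    @classmethod
    def from_records(cls, participant_id: str,
                     records: Sequence[StepRecord]) -> "KinematicTrial":
        return cls(
            participant_id,
            *(np.array([getattr(r, c) for r in records], dtype=float)
              for c in PELVIS_STATE_COLUMNS + FOOT_COLUMNS),
        )

    def records(self) -> list[StepRecord]:
        return [StepRecord(*row) for row in
                np.column_stack([self.pelvis_state(), self.foot_placement()])]


@dataclass
class JacobianFit:
    """Least-squares foot-placement gain matrix and its coefficient variances.

    ``gain[i, j]`` is the sensitivity of output ``i`` (x_foot, y_foot) to
    input ``j`` (x_pelvis, vx_pelvis, vy_pelvis); position-to-position
    entries are dimensionless, velocity-to-position entries carry seconds.
    ``coef_variance`` holds the squared standard errors from the regression.
    """

    participant_id: str
    gain: np.ndarray
    input_means: np.ndarray
    output_means: np.ndarray
    coef_variance: np.ndarray
    n_steps_used: int


@dataclass(frozen=True)
class BreathRecord:
    """One breath: time from trial start (s) and per-kg gas fluxes.

    ``vo2``/``vco2`` in mL s^-1 kg^-1; ``edot`` (W/kg) is derived via the
    Brockway equation, never read from disk.
    """

    t: float
    vo2: float
    vco2: float
    edot: float


@dataclass
class MetabolicTrial:
    """Breath-by-breath gas-exchange series for one participant."""

    participant_id: str
    condition: Literal["walking", "resting"]
    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    edot: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if self.condition not in ("walking", "resting"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("breath times must be non-decreasing")
        if self.edot is None:
            self.edot = brockway_rate(self.vo2, self.vco2)
        else:
            self.edot = np.asarray(self.edot, dtype=float)

    @property
    def n_breaths(self) -> int:
        return self.t.size

    def records(self) -> list[BreathRecord]:
        return [BreathRecord(*row) for row in
                np.column_stack([self.t, self.vo2, self.vco2, self.edot])]


@dataclass
class TransientFit:
    """Exponential steady-state fit ``Edot = a0 + a1*exp(-t/tau)``.

    ``a0`` (W/kg) is the steady-state asymptote; ``tau`` (s) the time
    constant.  ``converged`` reflects the optimizer status.
    """

    a0: float
    a1: float
    tau: float
    converged: bool
    n_points_used: int


@dataclass(frozen=True)
class PointEstimate:
    """A participant's MLE ``y_i`` with its error variance ``sigma_i^2``."""

    participant_id: str
    value: float
    variance: float
    n_used: int
    method: Literal["jacobian_element", "transient_a0", "resting_mean"]

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def brockway_rate(vo2, vco2):
    """Metabolic power (W/kg) from per-kg gas fluxes via the Brockway equation.

    ``Edot = 16.58*VO2 + 4.51*VCO2`` with fluxes in mL s^-1 kg^-1.
    Vectorizes over arrays; scalar in, scalar out.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    for name, arr in (("vo2", vo2), ("vco2", vco2)):
        bad = np.nonzero(np.atleast_1d(arr) < 0)[0]
        if bad.size:
            raise ValueError(
                f"negative {name} at sample index {int(bad[0])}: "
                f"{float(np.atleast_1d(arr)[bad[0]])}")
    out = BROCKWAY_O2 * vo2 + BROCKWAY_CO2 * vco2
    return float(out) if out.ndim == 0 else out


def fit_foot_placement_jacobian(trial: KinematicTrial,
                                n_steps: int | None = None) -> JacobianFit:
    """OLS fit of the 2x3 foot-placement gain matrix on the first ``n_steps``.

    Inputs and outputs are centered by their means over the truncated window
    (the window's own P*, S*), so the regression has no intercept and each
    output row has ``n_steps - 3`` residual degrees of freedom.  Coefficient
    variances come from the standard OLS formula
    ``Var(b) = s^2 * diag((X'X)^-1)`` with ``s^2 = RSS/(n-3)`` per row.
    """
    if n_steps is None:
        n_steps = trial.n_steps
    if n_steps < 7:
        raise ValueError("need at least 7 steps to fit 6 gains reliably")
    if n_steps > trial.n_steps:
        raise ValueError(
            f"requested {n_steps} steps but trial "
            f"{trial.participant_id!r} has only {trial.n_steps}")

    P = trial.pelvis_state()[:n_steps]
    S = trial.foot_placement()[:n_steps]
    p_star = P.mean(axis=0)
    s_star = S.mean(axis=0)
    X = P - p_star
    Y = S - s_star

    # rank check: name a degenerate (constant) column if there is one
    col_scale = np.abs(X).max(axis=0)
    for j, scale in enumerate(col_scale):
        if scale < 1e-12:
            raise ValueError(
                f"pelvis-state column {PELVIS_STATE_COLUMNS[j]!r} is constant "
                "over the window; gain matrix is not identifiable")
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("pelvis-state columns are collinear over the window; "
                         "gain matrix is not identifiable")

    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)  # (3, 2)
    resid = Y - X @ beta
    dof = n_steps - 3
    s2 = (resid ** 2).sum(axis=0) / dof               # per output row
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    coef_var = np.outer(s2, xtx_inv_diag)             # (2, 3)

    return JacobianFit(
        participant_id=trial.participant_id,
        gain=beta.T,
        input_means=p_star,
        output_means=s_star,
        coef_variance=coef_var,
        n_steps_used=n_steps,
    )


def extract_gain_element(fit: JacobianFit, out_index: int = 0,
                         in_index: int = 1) -> PointEstimate:
    """Package one gain-matrix element as a shrinkable point estimate.

    The default ``(0, 1)`` element is the sensitivity of sideways foot
    placement to sideways pelvis velocity at midstance, the usual target in
    foot-placement control analyses.
    """
    if not (0 <= out_index < 2 and 0 <= in_index < 3):
        raise IndexError(
            f"gain index ({out_index}, {in_index}) out of range for 2x3 matrix")
    return PointEstimate(
        participant_id=fit.participant_id,
        value=float(fit.gain[out_index, in_index]),
        variance=float(fit.coef_variance[out_index, in_index]),
        n_used=fit.n_steps_used,
        method="jacobian_element",
    )


def _exp_model(t, a0, a1, tau):
    return a0 + a1 * np.exp(-t / tau)


def fit_exponential_transient(trial: MetabolicTrial,
                              n_points: int | None = None) -> TransientFit:
    """Nonlinear least squares of the exponential transient on the first
    ``n_points`` breaths.

    Initialization: ``a0`` = mean of the last third of the window, ``a1`` =
    first sample minus ``a0``, ``tau`` = window span / 3.  ``tau`` is bounded
    to (0.1 s, 10x the window span).  An exactly flat window short-circuits
    to the sample mean with ``a1 = 0``; optimizer failure returns the initial
    iterate with ``converged=False``.
    """
    if n_points is None:
        n_points = trial.n_breaths
    if n_points < 4:
        raise ValueError("need at least 4 breaths to fit a 3-parameter model")
    if n_points > trial.n_breaths:
        raise ValueError(
            f"requested {n_points} breaths but trial "
            f"{trial.participant_id!r} has only {trial.n_breaths}")

    t = trial.t[:n_points]
    e = trial.edot[:n_points]
    span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    tau0 = span / 3.0
    a0_0 = float(e[-max(1, n_points // 3):].mean())
    a1_0 = float(e[0] - a0_0)

    if np.ptp(e) < 1e-12:  # flat signal: tau unidentifiable, mean suffices
        return TransientFit(float(e.mean()), 0.0, tau0, True, n_points)

    try:
        popt, _ = optimize.curve_fit(
            _exp_model, t, e,
            p0=[a0_0, a1_0, tau0],
            bounds=([-np.inf, -np.inf, 0.1], [np.inf, np.inf, 10.0 * span]),
            maxfev=2000,
        )
        return TransientFit(*map(float, popt), True, n_points)
    except RuntimeError:
        return TransientFit(a0_0, a1_0, tau0, False, n_points)


def steady_state_estimate(trial: MetabolicTrial, n_points: int | None = None,
                          n_boot: int = 1000, seed: int = 0) -> PointEstimate:
    """Steady-state metabolic rate ``a0`` with a bootstrap error variance.

    The variance is the empirical variance of ``a0`` over ``n_boot``
    case-resampled refits of the same window (breaths drawn with
    replacement, re-sorted by time).  Refits whose time constant exceeds
    the window span never observe their plateau, so their asymptote is an
    unconstrained extrapolation; they are censored from the variance as
    long as at least 30% of refits resolve a plateau inside the window,
    otherwise every converged refit is kept and the variance is honestly
    large.  Deterministic given ``seed``.

    Raises if more than 20% of bootstrap refits fail to converge, which
    signals that the window is too short for a stable transient fit.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    base = fit_exponential_transient(trial, n_points)
    n = base.n_points_used
    t = trial.t[:n]
    e = trial.edot[:n]

    span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    rng = np.random.default_rng(seed)
    a0s = np.full(n_boot, np.nan)
    taus = np.full(n_boot, np.nan)
    failed = 0
    for b in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))
        boot = MetabolicTrial(trial.participant_id, trial.condition,
                              t[idx], np.zeros(n), np.zeros(n), e[idx])
        fit = fit_exponential_transient(boot, n)
        if fit.converged:
            a0s[b] = fit.a0
            taus[b] = fit.tau
        else:
            failed += 1
    if failed > 0.2 * n_boot:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap refits failed to converge for "
            f"participant {trial.participant_id!r}; use a larger n_points")
    in_window = taus <= span  # nan-safe: excludes failures too
    if in_window.sum() >= 0.3 * n_boot:
        variance = float(np.var(a0s[in_window], ddof=1))
    else:
        variance = float(np.nanvar(a0s, ddof=1))
    return PointEstimate(trial.participant_id, float(base.a0), variance,
                         n, "transient_a0")


def resting_mean_estimate(trials: Sequence[MetabolicTrial],
                          n_points: int, n_boot: int = 1000,
                          seed: int = 0) -> list[PointEstimate]:
    """Resting metabolic rate per participant with a pooled bootstrap variance.

    Each participant's value is the mean metabolic power over their first
    ``n_points`` breaths.  A single error variance is shared by the whole
    cohort: deviations from each participant's own window mean are pooled
    across participants, and the squared standard error of an
    ``n_points``-sample mean is the variance, over ``n_boot`` draws, of the
    mean of ``n_points`` deviations resampled with replacement from the pool.
    """
    if not trials:
        raise ValueError("no trials supplied")
    bad = [tr.participant_id for tr in trials if tr.condition != "resting"]
    if bad:
        raise ValueError(f"non-resting trials in input: {bad}")
    short = [tr.participant_id for tr in trials if tr.n_breaths < n_points]
    if short:
        raise ValueError(f"trials shorter than n_points={n_points}: {short}")
    if n_points < 2:
        raise ValueError("need at least 2 breaths for a resting mean")

    means = np.array([tr.edot[:n_points].mean() for tr in trials])
    pooled = np.concatenate([tr.edot[:n_points] - m
                             for tr, m in zip(trials, means)])

    rng = np.random.default_rng(seed)
    draws = rng.choice(pooled, size=(n_boot, n_points), replace=True)
    se2 = float(draws.mean(axis=1).var(ddof=1))

    return [PointEstimate(tr.participant_id, float(m), se2, n_points,
                          "resting_mean")
            for tr, m in zip(trials, means)]
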