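"""Synthetic cohorts with known ground truth.

Two generators mirror the statistical structure the estimators assume, so
every downstream stage is testable without any experimental download:

* :func:`simulate_kinematic_cohort` — each participant gets a true 2x3
  foot-placement gain matrix drawn from a Gaussian population; each step
  draws a midstance pelvis-state deviation from a fixed covariance and sets
  the next foot placement as the linear response plus Gaussian step noise.
* :func:`simulate_metabolic_cohort` — each participant gets true
  ``(a0, a1, tau)`` drawn from Gaussian populations; metabolic power follows
  the exponential transient ``a0 + a1*exp(-t/tau)`` sampled at jittered
  breath intervals with additive noise.  A gas-flux pair is back-computed at
  a fixed respiratory exchange ratio so the Brockway conversion is exercised
  end to end.  ``resting_mode`` forces ``a1 = 0`` (quiet sitting).

Defaults echo the scale of treadmill/circle-walking/sitting studies: cohorts
of 8 / 11 / 27 participants, 100-step walking trials, and 6.5-minute
metabolic trials yielding at least 54 walking or 40 resting breaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .estimators import BROCKWAY_CO2, BROCKWAY_O2, KinematicTrial, MetabolicTrial

__all__ = [
    "KinematicCohortSpec",
    "MetabolicCohortSpec",
    "SyntheticTruth",
    "DEFAULT_GAIN_ELEMENT",
    "simulate_kinematic_cohort",
    "simulate_metabolic_cohort",
    "default_kinematic_spec",
    "default_walking_spec",
    "default_resting_spec",
]

#: (output row, input column) of the gain element treated as the estimand:
#: sideways foot placement vs sideways pelvis velocity at midstance.
DEFAULT_GAIN_ELEMENT = (0, 1)

_DEFAULT_GAIN_MEAN = np.array([[0.45, 0.30, 0.05],
                               [0.00, 0.05, 0.35]])
_DEFAULT_GAIN_SD = np.array([[0.05, 0.06, 0.02],
                             [0.02, 0.02, 0.05]])
# midstance pelvis-state deviations: sd 10 mm sideways position,
# 50 mm/s sideways velocity, 40 mm/s forward velocity
_DEFAULT_PELVIS_COV = np.diag([0.010 ** 2, 0.050 ** 2, 0.040 ** 2])


@dataclass(frozen=True)
class KinematicCohortSpec:
    """Generative description of a walking cohort.

    ``population_gain_mean``/``population_gain_sd`` give the between-
    participant distribution of the 2x3 gain matrix (dimensionless and
    s-valued sensitivities); ``pelvis_state_cov`` the 3x3 covariance of
    midstance pelvis-state deviations (m, m/s, m/s); ``step_noise_sd`` the
    per-output residual sd of foot placement (m).
    """

    n_participants: int = 8
    n_steps: int = 100
    population_gain_mean: np.ndarray = field(
        default_factory=_DEFAULT_GAIN_MEAN.copy)
    population_gain_sd: np.ndarray = field(
        default_factory=_DEFAULT_GAIN_SD.copy)
    pelvis_state_cov: np.ndarray = field(
        default_factory=_DEFAULT_PELVIS_COV.copy)
    step_noise_sd: float = 0.008
    pelvis_state_mean: tuple[float, float, float] = (0.0, 0.0, 1.3)
    foot_mean: tuple[float, float] = (0.05, 0.72)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be >= 4 (k-3 > 0)")
        if self.n_steps < 7:
            raise ValueError("n_steps must be >= 7")
        gm = np.asarray(self.population_gain_mean, dtype=float)
        gs = np.asarray(self.population_gain_sd, dtype=float)
        if gm.shape != (2, 3) or gs.shape != (2, 3):
            raise ValueError("population gain mean/sd must be 2x3")
        if np.any(gs < 0):
            raise ValueError("population_gain_sd must be non-negative")
        if self.step_noise_sd < 0:
            raise ValueError("step_noise_sd must be non-negative")
        cov = np.asarray(self.pelvis_state_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("pelvis_state_cov must be symmetric 3x3")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("pelvis_state_cov must be positive-definite")
        object.__setattr__(self, "population_gain_mean", gm)
        object.__setattr__(self, "population_gain_sd", gs)
        object.__setattr__(self, "pelvis_state_cov", cov)


@dataclass(frozen=True)
class MetabolicCohortSpec:
    """Generative description of a breath-by-breath metabolic cohort.

    Metabolic power (W/kg) follows ``a0 + a1*exp(-t/tau)`` plus Gaussian
    measurement noise, sampled at jittered breath intervals (s) over
    ``trial_duration``.  ``resting_mode`` forces ``a1 = 0`` and marks trials
    as quiet sitting.  ``rer`` is the fixed respiratory exchange ratio
    (VCO2/VO2) used to back-compute a gas-flux pair from each power sample.
    """

    n_participants: int = 11
    trial_duration: float = 390.0
    mean_breath_interval: float = 6.5
    breath_interval_jitter_sd: float = 1.2
    population_a0_mean: float = 5.0
    population_a0_sd: float = 0.5
    population_a1_mean: float = -3.5
    population_a1_sd: float = 0.5
    population_tau_mean: float = 30.0
    population_tau_sd: float = 8.0
    measurement_noise_sd: float = 0.25
    resting_mode: bool = False
    rer: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be >= 4 (k-3 > 0)")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.population_tau_mean <= 0:
            raise ValueError("population_tau_mean must be positive")
        if self.mean_breath_interval <= 0:
            raise ValueError("mean_breath_interval must be positive")
        if self.trial_duration < 3 * self.mean_breath_interval:
            raise ValueError("trial_duration must cover at least 3 mean "
                             "breath intervals (too few samples to fit)")
        if min(self.population_a0_sd, self.population_a1_sd,
               self.population_tau_sd, self.measurement_noise_sd,
               self.breath_interval_jitter_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.rer <= 0:
            raise ValueError("rer must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """A participant's generative truth: the scalar target of estimation
    (one gain element, steady-state a0, or resting mean) plus the full
    generative parameters for reference."""

    participant_id: str
    true_parameter: float
    units: str
    params: dict


def simulate_kinematic_cohort(spec: KinematicCohortSpec,
                              ) -> tuple[list[KinematicTrial],
                                         list[SyntheticTruth]]:
    """Draw a cohort of step-level walking trials with known gain matrices.

    Deterministic given ``spec.seed``.  The reported truth is the
    :data:`DEFAULT_GAIN_ELEMENT` entry of each participant's true matrix;
    the full matrix is kept in ``SyntheticTruth.params``.
    """
    rng = np.random.default_rng(spec.seed)
    trials: list[KinematicTrial] = []
    truths: list[SyntheticTruth] = []
    chol = np.linalg.cholesky(spec.pelvis_state_cov)
    out_i, in_i = DEFAULT_GAIN_ELEMENT
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        gain = rng.normal(spec.population_gain_mean, spec.population_gain_sd)
        dP = rng.standard_normal((spec.n_steps, 3)) @ chol.T
        eps = rng.normal(0.0, spec.step_noise_sd, size=(spec.n_steps, 2))
        dS = dP @ gain.T + eps
        P = dP + np.asarray(spec.pelvis_state_mean)
        S = dS + np.asarray(spec.foot_mean)
        trials.append(KinematicTrial(pid, P[:, 0], P[:, 1], P[:, 2],
                                     S[:, 0], S[:, 1]))
        truths.append(SyntheticTruth(
            pid, float(gain[out_i, in_i]), "s",
            {"gain": gain.tolist(),
             "element": [out_i, in_i]}))
    return trials, truths


def simulate_metabolic_cohort(spec: MetabolicCohortSpec,
                              ) -> tuple[list[MetabolicTrial],
                                         list[SyntheticTruth]]:
    """Draw a cohort of breath-by-breath metabolic trials with known
    ``(a0, a1, tau)``.

    Breath timestamps accumulate jittered intervals until the trial
    duration; non-positive intervals are redrawn.  ``tau`` draws are redrawn
    while non-positive.  The gas pair is back-computed from the noisy power
    sample at the fixed RER, so converting it back through the Brockway
    equation reproduces the emitted power exactly.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    condition = "resting" if spec.resting_mode else "walking"
    # Brockway with VCO2 = rer * VO2 collapses to a single coefficient
    per_vo2 = BROCKWAY_O2 + BROCKWAY_CO2 * spec.rer

    trials: list[MetabolicTrial] = []
    truths: list[SyntheticTruth] = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        a0 = rng.normal(spec.population_a0_mean, spec.population_a0_sd)
        a1 = 0.0 if spec.resting_mode else rng.normal(
            spec.population_a1_mean, spec.population_a1_sd)
        tau = rng.normal(spec.population_tau_mean, spec.population_tau_sd)
        while tau <= 0:
            tau = rng.normal(spec.population_tau_mean, spec.population_tau_sd)

        times = []
        t = 0.0
        while True:
            dt = rng.normal(spec.mean_breath_interval,
                            spec.breath_interval_jitter_sd)
            while dt <= 0:
                dt = rng.normal(spec.mean_breath_interval,
                                spec.breath_interval_jitter_sd)
            t += dt
            if t > spec.trial_duration:
                break
            times.append(t)
        tarr = np.array(times)

        edot = a0 + a1 * np.exp(-tarr / tau)
        edot = edot + rng.normal(0.0, spec.measurement_noise_sd,
                                 size=tarr.size)
        edot = np.maximum(edot, 0.0)  # gas fluxes cannot be negative
        vo2 = edot / per_vo2
        vco2 = spec.rer * vo2
        trials.append(MetabolicTrial(pid, condition, tarr, vo2, vco2, edot))
        truths.append(SyntheticTruth(
            pid, float(a0), "W/kg",
            {"a0": float(a0), "a1": float(a1), "tau": float(tau),
             "rer": spec.rer}))
    return trials, truths


def default_kinematic_spec(seed: int = 0, **overrides) -> KinematicCohortSpec:
    """Treadmill-walking cohort defaults: k=8 participants, 100 steps."""
    return replace(KinematicCohortSpec(seed=seed), **overrides)


def default_walking_spec(seed: int = 0, **overrides) -> MetabolicCohortSpec:
    """Circle-walking metabolic cohort defaults: k=11, ~60 breaths."""
    return replace(MetabolicCohortSpec(seed=seed), **overrides)


def default_resting_spec(seed: int = 0, **overrides) -> MetabolicCohortSpec:
    """Quiet-sitting cohort defaults: k=27, low within-participant noise
    relative to between-participant spread, ~45 breaths."""
    base = MetabolicCohortSpec(
        n_participants=27,
        mean_breath_interval=8.5,
        breath_interval_jitter_sd=1.5,
        population_a0_mean=1.5,
        population_a0_sd=0.15,
        population_a1_mean=0.0,
        population_a1_sd=0.0,
        measurement_noise_sd=0.10,
        resting_mode=True,
        seed=seed,
    )
    return replace(base, **overrides)
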