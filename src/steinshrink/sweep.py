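"""Trial-duration (truncation) sweeps.

For each truncation length ``n`` in a grid, compute every participant's MLE
from the first ``n`` records, shrink the cohort toward its grand mean, and
score both estimators against a per-participant truth.  The truth is, by
default, the estimate from the full available trial (the longest-duration
proxy, since the real true value is unknowable); in *recovery mode* a
supplied generative truth is used instead, which is only possible on
synthetic cohorts.

The decay of the shrunk estimator's summed squared error with ``n`` is
summarized by ``SSE = amplitude * exp(-rate * n)``, fitted by ordinary least
squares on the log-transformed SSEs.

:func:`recovery_study` repeats generate-and-sweep many times against the
generative truth, yielding the expected accuracy-vs-duration curves and the
fraction of replicates where shrinkage helps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    KinematicTrial,
    MetabolicTrial,
    PointEstimate,
    extract_gain_element,
    fit_foot_placement_jacobian,
    resting_mean_estimate,
    steady_state_estimate,
)
from .shrinkage import (
    AccuracyComparison,
    CohortEstimates,
    ShrinkageResult,
    compare_accuracy,
    compute_shrinkage,
)
from .synthetic import (
    KinematicCohortSpec,
    MetabolicCohortSpec,
    SyntheticTruth,
    simulate_kinematic_cohort,
    simulate_metabolic_cohort,
)

__all__ = [
    "SweepSpec",
    "DecayFit",
    "SweepResult",
    "RecoveryResult",
    "default_grid",
    "run_sweep",
    "fit_sse_decay",
    "recovery_study",
]

DatasetKind = Literal["kinematic", "walking_metabolic", "resting_metabolic"]

#: default truncation grids and truth sizes per dataset kind: steps for
#: kinematics (15..90 by 5 against 100), breaths for metabolics (15..51 by 3
#: against 54 walking; 10..34 by 3 against 40 resting)
DEFAULT_GRIDS: dict[str, tuple[list[int], int]] = {
    "kinematic": (list(range(15, 91, 5)), 100),
    "walking_metabolic": (list(range(15, 52, 3)), 54),
    "resting_metabolic": (list(range(10, 36, 3)), 40),
}


def default_grid(kind: DatasetKind) -> tuple[list[int], int]:
    grid, truth = DEFAULT_GRIDS[kind]
    return list(grid), truth


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep: dataset kind, truncation grid, truth size, options."""

    dataset_kind: DatasetKind
    truncation_grid: tuple[int, ...] = ()
    truth_size: int = 0
    n_boot: int = 200
    seed: int = 0
    positive_part: bool = True
    gain_element: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.dataset_kind not in DEFAULT_GRIDS:
            raise ValueError(f"unknown dataset_kind {self.dataset_kind!r}")
        grid, truth = (list(self.truncation_grid), self.truth_size)
        if not grid:
            grid, default_truth = default_grid(self.dataset_kind)
            truth = truth or default_truth
        if truth <= 0:
            raise ValueError("truth_size must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("truncation_grid must be strictly increasing")
        if grid[-1] >= truth:
            raise ValueError("every grid value must be below truth_size")
        object.__setattr__(self, "truncation_grid", tuple(grid))
        object.__setattr__(self, "truth_size", int(truth))


@dataclass
class DecayFit:
    """``SSE(n) = amplitude * exp(-rate * n)`` from a log-linear fit."""

    amplitude: float
    rate: float
    n_points_used: int


@dataclass
class SweepResult:
    spec: SweepSpec
    grid: np.ndarray
    shrinkages: list[ShrinkageResult]
    comparisons: list[AccuracyComparison]
    estimates: list[list[PointEstimate]]
    truth_estimates: list[PointEstimate] | None
    truth_values: np.ndarray
    participant_ids: list[str]
    decay_fit: DecayFit | None

    @property
    def sse_mle(self) -> np.ndarray:
        return np.array([c.sse_mle for c in self.comparisons])

    @property
    def sse_jse(self) -> np.ndarray:
        return np.array([c.sse_jse for c in self.comparisons])

    @property
    def pct_reduction(self) -> np.ndarray:
        return np.array([c.pct_reduction for c in self.comparisons])

    @property
    def raw_c(self) -> np.ndarray:
        return np.array([s.raw_c for s in self.shrinkages])

    @property
    def applied_c(self) -> np.ndarray:
        return np.array([s.applied_c for s in self.shrinkages])

    def summary_frame(self) -> pd.DataFrame:
        """One row per grid value plus a truth row (zero error by
        construction when the truth is the full-duration estimate)."""
        rows = pd.DataFrame({
            "n": self.grid,
            "sse_mle": self.sse_mle,
            "sse_jse": self.sse_jse,
            "pct_reduction": self.pct_reduction,
            "raw_c": self.raw_c,
            "applied_c": self.applied_c,
            "is_truth": False,
        })
        truth_row = pd.DataFrame({
            "n": [self.spec.truth_size], "sse_mle": [np.nan],
            "sse_jse": [np.nan], "pct_reduction": [np.nan],
            "raw_c": [np.nan], "applied_c": [np.nan], "is_truth": [True],
        })
        return pd.concat([rows, truth_row], ignore_index=True)

    def tidy_frame(self) -> pd.DataFrame:
        """One row per (grid value, participant): y, z, x."""
        records = []
        for n, ests, shrink, comp in zip(self.grid, self.estimates,
                                         self.shrinkages, self.comparisons):
            for e, z, x in zip(ests, shrink.shrunk_values, comp.truths):
                records.append({
                    "dataset_kind": self.spec.dataset_kind,
                    "n": int(n), "participant_id": e.participant_id,
                    "y_mle": e.value, "z_jse": float(z), "x_truth": float(x),
                    "variance": e.variance,
                })
        return pd.DataFrame.from_records(records)


def _child_seed(root: int, *path: int) -> int:
    """Deterministic per-(participant, grid, replicate) seed below 2^31."""
    ss = np.random.SeedSequence([int(root) & 0x7FFFFFFF,
                                 *(int(p) & 0x7FFFFFFF for p in path)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _estimate_cohort(trials, spec: SweepSpec, n: int,
                     grid_index: int) -> list[PointEstimate]:
    kind = spec.dataset_kind
    if kind == "kinematic":
        out_i, in_i = spec.gain_element
        return [extract_gain_element(fit_foot_placement_jacobian(tr, n),
                                     out_i, in_i) for tr in trials]
    if kind == "walking_metabolic":
        return [steady_state_estimate(
                    tr, n, n_boot=spec.n_boot,
                    seed=_child_seed(spec.seed, grid_index, j))
                for j, tr in enumerate(trials)]
    return resting_mean_estimate(trials, n, n_boot=spec.n_boot,
                                 seed=_child_seed(spec.seed, grid_index))


def run_sweep(trials: Sequence[KinematicTrial] | Sequence[MetabolicTrial],
              spec: SweepSpec,
              truths: Sequence[SyntheticTruth] | None = None) -> SweepResult:
    """Run the truncation sweep over one cohort.

    Without ``truths``, the per-participant truth is the estimate at
    ``spec.truth_size`` records (full-duration proxy); with ``truths``,
    generative values are used (recovery mode).
    """
    sizes = {tr.participant_id:
             (tr.n_steps if isinstance(tr, KinematicTrial) else tr.n_breaths)
             for tr in trials}
    short = [pid for pid, size in sizes.items() if size < spec.truth_size]
    if short:
        raise ValueError(
            f"participants shorter than truth_size={spec.truth_size}: {short}")

    ids = [tr.participant_id for tr in trials]
    truth_estimates = None
    if truths is not None:
        by_id = {t.participant_id: t.true_parameter for t in truths}
        missing = set(ids) - set(by_id)
        if missing:
            raise ValueError(f"no generative truth for: {sorted(missing)}")
        truth_values = np.array([by_id[i] for i in ids])
    else:
        truth_estimates = _estimate_cohort(trials, spec, spec.truth_size, -1)
        truth_values = np.array([e.value for e in truth_estimates])

    shrinkages, comparisons, estimates = [], [], []
    for gi, n in enumerate(spec.truncation_grid):
        ests = _estimate_cohort(trials, spec, int(n), gi)
        cohort = CohortEstimates(ests)
        shrink = compute_shrinkage(cohort, positive_part=spec.positive_part)
        comp = compare_accuracy(truth_values, cohort, shrink)
        estimates.append(ests)
        shrinkages.append(shrink)
        comparisons.append(comp)

    sse_jse = np.array([c.sse_jse for c in comparisons])
    decay = None
    if np.any(sse_jse > 0) and (sse_jse > 0).sum() >= 3:
        decay = fit_sse_decay(np.asarray(spec.truncation_grid), sse_jse)

    return SweepResult(
        spec=spec, grid=np.asarray(spec.truncation_grid),
        shrinkages=shrinkages, comparisons=comparisons, estimates=estimates,
        truth_estimates=truth_estimates, truth_values=truth_values,
        participant_ids=ids, decay_fit=decay,
    )


def fit_sse_decay(grid, sse) -> DecayFit:
    """Log-linear fit of ``SSE = amplitude * exp(-rate * n)``.

    Non-positive SSEs cannot be log-transformed; they are dropped with a
    warning, and fewer than 3 surviving points is an error.
    """
    grid = np.asarray(grid, dtype=float)
    sse = np.asarray(sse, dtype=float)
    keep = sse > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} non-positive SSE "
                      "values before log-linear decay fit", stacklevel=2)
    grid, sse = grid[keep], sse[keep]
    if grid.size < 3:
        raise ValueError("need at least 3 positive SSE values to fit decay")
    slope, intercept = np.polyfit(grid, np.log(sse), 1)
    return DecayFit(amplitude=float(np.exp(intercept)), rate=float(-slope),
                    n_points_used=int(grid.size))


@dataclass
class RecoveryResult:
    """Expected accuracy-vs-duration curves over fresh synthetic cohorts.

    ``mean_pct_reduction`` averages per-replicate percent reductions;
    ``pooled_pct_reduction`` is computed from the mean SSE curves and is the
    stabler of the two.
    """

    grid: np.ndarray
    n_reps: int
    mean_sse_mle: np.ndarray
    mean_sse_jse: np.ndarray
    mean_pct_reduction: np.ndarray
    pooled_pct_reduction: np.ndarray
    mean_applied_c: np.ndarray
    frac_positive_reduction: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.grid,
            "mean_sse_mle": self.mean_sse_mle,
            "mean_sse_jse": self.mean_sse_jse,
            "mean_pct_reduction": self.mean_pct_reduction,
            "pooled_pct_reduction": self.pooled_pct_reduction,
            "mean_applied_c": self.mean_applied_c,
            "frac_positive_reduction": self.frac_positive_reduction,
        })


def recovery_study(cohort_spec: KinematicCohortSpec | MetabolicCohortSpec,
                   sweep_spec: SweepSpec, n_reps: int = 200,
                   seed: int = 0) -> RecoveryResult:
    """Repeat generate-and-sweep against the generative truth.

    Each replicate regenerates the cohort with a derived seed and sweeps it;
    curves are averaged across replicates.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    is_kin = isinstance(cohort_spec, KinematicCohortSpec)
    if is_kin != (sweep_spec.dataset_kind == "kinematic"):
        raise ValueError("cohort spec and sweep dataset_kind disagree")

    grid = np.asarray(sweep_spec.truncation_grid)
    sse_mle = np.empty((n_reps, grid.size))
    sse_jse = np.empty((n_reps, grid.size))
    pct = np.empty((n_reps, grid.size))
    cval = np.empty((n_reps, grid.size))
    for r in range(n_reps):
        cspec = replace(cohort_spec, seed=_child_seed(seed, r))
        if is_kin:
            trials, truths = simulate_kinematic_cohort(cspec)
        else:
            trials, truths = simulate_metabolic_cohort(cspec)
        sspec = replace(sweep_spec, seed=_child_seed(seed, r, 1))
        res = run_sweep(trials, sspec, truths=truths)
        sse_mle[r] = res.sse_mle
        sse_jse[r] = res.sse_jse
        pct[r] = res.pct_reduction
        cval[r] = res.applied_c

    mean_mle = sse_mle.mean(axis=0)
    mean_jse = sse_jse.mean(axis=0)
    return RecoveryResult(
        grid=grid, n_reps=n_reps,
        mean_sse_mle=mean_mle, mean_sse_jse=mean_jse,
        mean_pct_reduction=pct.mean(axis=0),
        pooled_pct_reduction=100.0 * (mean_mle - mean_jse) / mean_mle,
        mean_applied_c=cval.mean(axis=0),
        frac_positive_reduction=(sse_jse < sse_mle).mean(axis=0),
    )
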