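"""Per-participant MLEs at the short-trial snapshot sizes and at full length.

Reads the cohorts exported by 01_simulate_cohorts.py, computes each
participant's point estimate and error variance at the snapshot truncation
(25 steps / 21 breaths / 20 breaths) and at the full truth size
(100 / 54 / 40), and writes tidy point-estimate CSVs under
results/estimates/.  Run 01 first.
"""

from pathlib import Path

import steinshrink as ss
from steinshrink import io

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
SNAPSHOTS = {"kinematic": (25, 100), "walking": (21, 54), "resting": (20, 40)}


def estimate(kind, trials, n, seed):
    if kind == "kinematic":
        return [ss.extract_gain_element(ss.fit_foot_placement_jacobian(tr, n))
                for tr in trials]
    if kind == "walking":
        return [ss.steady_state_estimate(tr, n, n_boot=1000, seed=seed + j)
                for j, tr in enumerate(trials)]
    return ss.resting_mean_estimate(trials, n, n_boot=1000, seed=seed)


def main():
    out = ROOT / "estimates"
    out.mkdir(parents=True, exist_ok=True)
    for kind, (n_short, n_truth) in SNAPSHOTS.items():
        src = ROOT / "data" / kind
        if kind == "kinematic":
            trials = io.read_kinematic_csv(src / "steps.csv")
        else:
            trials = io.read_metabolic_csv(src / "breaths.csv")
        for label, n in (("short", n_short), ("truth", n_truth)):
            ests = estimate(kind, trials, n, SEED)
            path = out / f"{kind}_{label}_n{n}.csv"
            io.write_point_estimates_csv(ests, path)
            vals = [e.value for e in ests]
            print(f"{kind} {label} (n={n}): k={len(ests)}, "
                  f"mean={sum(vals)/len(vals):.4g} -> {path.name}")


if __name__ == "__main__":
    main()
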