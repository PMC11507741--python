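"""Generate the three default synthetic cohorts and export them as CSV.

Produces, under results/data/:
  kinematic/   8 treadmill-walking participants, 100 steps each
  walking/     11 circle-walking participants, breath-by-breath metabolics
  resting/     27 quiet-sitting participants, breath-by-breath metabolics
plus a JSON manifest per cohort recording the generative spec and the
per-participant ground truth.
"""

from pathlib import Path

import steinshrink as ss
from steinshrink import io

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    spec = ss.default_kinematic_spec(seed=SEED)
    trials, truths = ss.simulate_kinematic_cohort(spec)
    d = OUT / "kinematic"
    d.mkdir(exist_ok=True)
    io.write_kinematic_csv(trials, d / "steps.csv")
    io.write_cohort_manifest(d / "cohort_manifest.json", spec, truths,
                             {"data": "steps.csv"})
    print(f"kinematic: k={len(trials)}, {trials[0].n_steps} steps each "
          f"-> {d/'steps.csv'}")

    for name, maker in (("walking", ss.default_walking_spec),
                        ("resting", ss.default_resting_spec)):
        spec = maker(seed=SEED)
        trials, truths = ss.simulate_metabolic_cohort(spec)
        d = OUT / name
        d.mkdir(exist_ok=True)
        io.write_metabolic_csv(trials, d / "breaths.csv")
        io.write_cohort_manifest(d / "cohort_manifest.json", spec, truths,
                                 {"data": "breaths.csv"})
        counts = [t.n_breaths for t in trials]
        print(f"{name}: k={len(trials)}, {min(counts)}-{max(counts)} breaths "
              f"-> {d/'breaths.csv'}")


if __name__ == "__main__":
    main()
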