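"""Accuracy versus trial duration: the full truncation sweeps.

Sweeps each exported cohort over its truncation grid (15-90 steps, 15-51
walking breaths, 10-34 resting breaths), scoring against the full-duration
truth proxy, and fits the exponential decay of the shrunk estimator's SSE.
Writes summary/tidy CSVs and decay-fit JSONs under results/sweeps/, plus a
three-row figure (SSEs, percent reduction, shrinkage factor) if matplotlib
is available.
"""

import dataclasses
import json
from pathlib import Path

import steinshrink as ss
from steinshrink import io

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
KINDS = {"kinematic": "kinematic", "walking": "walking_metabolic",
         "resting": "resting_metabolic"}


def main():
    out = ROOT / "sweeps"
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for name, kind in KINDS.items():
        src = ROOT / "data" / name
        if name == "kinematic":
            trials = io.read_kinematic_csv(src / "steps.csv")
        else:
            trials = io.read_metabolic_csv(src / "breaths.csv")
        spec = ss.SweepSpec(dataset_kind=kind, n_boot=300, seed=SEED)
        res = ss.run_sweep(trials, spec)
        results[name] = res
        res.summary_frame().to_csv(out / f"{name}_summary.csv", index=False)
        res.tidy_frame().to_csv(out / f"{name}_tidy.csv", index=False)
        if res.decay_fit is not None:
            (out / f"{name}_decay.json").write_text(json.dumps(
                dataclasses.asdict(res.decay_fit), indent=2))
            print(f"{name}: SSE(n) ~ {res.decay_fit.amplitude:.3g} * "
                  f"exp(-{res.decay_fit.rate:.4f} n); "
                  f"c: {res.applied_c[0]:.3f} -> {res.applied_c[-1]:.3f}")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping figure")
        return
    fig, axes = plt.subplots(3, 3, figsize=(12, 9), sharex="col")
    for col, (name, res) in enumerate(results.items()):
        n = res.grid
        axes[0, col].plot(n, res.sse_mle, "o-", label="MLE")
        axes[0, col].plot(n, res.sse_jse, "s-", label="JSE")
        if res.decay_fit is not None:
            import numpy as np
            axes[0, col].plot(n, res.decay_fit.amplitude *
                              np.exp(-res.decay_fit.rate * n), "--",
                              label="decay fit")
        axes[0, col].set_title(name)
        axes[0, col].set_ylabel("SSE")
        axes[0, col].legend(fontsize=8)
        axes[1, col].axhline(0, color="gray", lw=0.5)
        axes[1, col].plot(n, res.pct_reduction, "o-")
        axes[1, col].set_ylabel("% SSE reduction")
        axes[2, col].plot(n, res.applied_c, "o-")
        axes[2, col].set_ylabel("shrinkage factor c")
        axes[2, col].set_xlabel("records used")
        axes[2, col].set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(out / "duration_sweeps.png", dpi=120)
    print(f"figure -> {out/'duration_sweeps.png'}")


if __name__ == "__main__":
    main()
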