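"""Shrink the snapshot MLEs toward the cohort mean and score the change.

For each cohort, shrinks the short-window estimates from
02_participant_estimates.py toward their grand mean, and compares both MLE
and shrunk estimates against the full-window (truth-proxy) estimates:
shrinkage factor c, SSEs, percent reduction, and the paired tests.  Writes
results/shrinkage/<kind>_snapshot.json and a per-participant table.
"""

import json
from pathlib import Path

import pandas as pd

import steinshrink as ss
from steinshrink import io

ROOT = Path(__file__).resolve().parent.parent / "results"
SNAPSHOTS = {"kinematic": (25, 100), "walking": (21, 54), "resting": (20, 40)}


def main():
    out = ROOT / "shrinkage"
    out.mkdir(parents=True, exist_ok=True)
    for kind, (n_short, n_truth) in SNAPSHOTS.items():
        est_dir = ROOT / "estimates"
        cohort = ss.CohortEstimates(io.read_point_estimates_csv(
            est_dir / f"{kind}_short_n{n_short}.csv"))
        truth_ests = io.read_point_estimates_csv(
            est_dir / f"{kind}_truth_n{n_truth}.csv")
        truths = {e.participant_id: e.value for e in truth_ests}

        result = ss.compute_shrinkage(cohort)
        comp = ss.compare_accuracy(truths, cohort, result)

        summary = {
            "kind": kind, "k": cohort.k, "n_short": n_short,
            "n_truth": n_truth,
            "applied_c": result.applied_c, "raw_c": result.raw_c,
            "grand_mean": result.grand_mean,
            "pooled_se2": result.pooled_se2,
            "sse_mle": comp.sse_mle, "sse_jse": comp.sse_jse,
            "pct_reduction": comp.pct_reduction,
            "p_paired_sq_errors": comp.p_paired_sq_errors,
            "p_truth_vs_mle": comp.p_truth_vs_mle,
        }
        (out / f"{kind}_snapshot.json").write_text(
            json.dumps(summary, indent=2))
        pd.DataFrame({
            "participant_id": cohort.participant_ids,
            "y_mle": cohort.values(),
            "z_jse": result.shrunk_values,
            "x_truth": comp.truths,
        }).to_csv(out / f"{kind}_snapshot.csv", index=False)
        print(f"{kind}: c={result.applied_c:.3f}, "
              f"SSE {comp.sse_mle:.4g} -> {comp.sse_jse:.4g} "
              f"({comp.pct_reduction:+.1f}%), p={comp.p_paired_sq_errors:.3f}")


if __name__ == "__main__":
    main()
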