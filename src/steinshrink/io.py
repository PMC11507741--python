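"""Readers and writers for the package's tidy CSV/JSON dialects.

Kinematic CSV: one row per step —
``participant_id, step_index, x_pelvis, vx_pelvis, vy_pelvis, x_foot, y_foot``
(SI units, header required).

Metabolic CSV: one row per breath —
``participant_id, condition, t_s, vo2_mls_kg, vco2_mls_kg``.  Metabolic
power is always recomputed through the Brockway equation, never read.

Point estimates serialize to
``participant_id, method, n_used, value, variance``.

:func:`load_external_tables` adapts a third-party deposit (e.g. a public
data-archive download) whose exact schema is unknown ahead of time: a
YAML/JSON column map names the files and maps their columns onto the
dialects above.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

import numpy as np

from .estimators import KinematicTrial, MetabolicTrial, PointEstimate

__all__ = [
    "write_kinematic_csv",
    "read_kinematic_csv",
    "write_metabolic_csv",
    "read_metabolic_csv",
    "write_point_estimates_csv",
    "read_point_estimates_csv",
    "write_cohort_manifest",
    "load_external_tables",
]

KINEMATIC_COLUMNS = ["participant_id", "step_index", "x_pelvis", "vx_pelvis",
                     "vy_pelvis", "x_foot", "y_foot"]
METABOLIC_COLUMNS = ["participant_id", "condition", "t_s", "vo2_mls_kg",
                     "vco2_mls_kg"]


def write_kinematic_csv(trials: Sequence[KinematicTrial], path) -> None:
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "step_index": np.arange(tr.n_steps),
            "x_pelvis": tr.x_pelvis, "vx_pelvis": tr.vx_pelvis,
            "vy_pelvis": tr.vy_pelvis,
            "x_foot": tr.x_foot, "y_foot": tr.y_foot,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _kinematic_trials_from_frame(df: pd.DataFrame, source) -> list[KinematicTrial]:
    missing = set(KINEMATIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinematic table {source} missing columns: "
                         f"{sorted(missing)}")
    trials = []
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("step_index")
        trials.append(KinematicTrial(
            str(pid), g["x_pelvis"].to_numpy(), g["vx_pelvis"].to_numpy(),
            g["vy_pelvis"].to_numpy(), g["x_foot"].to_numpy(),
            g["y_foot"].to_numpy()))
    return trials


def read_kinematic_csv(path) -> list[KinematicTrial]:
    return _kinematic_trials_from_frame(pd.read_csv(path), path)


def write_metabolic_csv(trials: Sequence[MetabolicTrial], path) -> None:
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "condition": tr.condition,
            "t_s": tr.t, "vo2_mls_kg": tr.vo2, "vco2_mls_kg": tr.vco2,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _metabolic_trials_from_frame(df: pd.DataFrame, source) -> list[MetabolicTrial]:
    missing = set(METABOLIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metabolic table {source} missing columns: "
                         f"{sorted(missing)}")
    trials = []
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("t_s")
        conditions = g["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"participant {pid} mixes conditions "
                             f"{list(conditions)} in one file")
        trials.append(MetabolicTrial(
            str(pid), str(conditions[0]), g["t_s"].to_numpy(),
            g["vo2_mls_kg"].to_numpy(), g["vco2_mls_kg"].to_numpy()))
    return trials


def read_metabolic_csv(path) -> list[MetabolicTrial]:
    return _metabolic_trials_from_frame(pd.read_csv(path), path)


def write_point_estimates_csv(estimates: Sequence[PointEstimate],
                              path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in estimates])[
        ["participant_id", "method", "n_used", "value", "variance"]
    ].to_csv(path, index=False)


def read_point_estimates_csv(path) -> list[PointEstimate]:
    df = pd.read_csv(path)
    required = {"participant_id", "method", "n_used", "value", "variance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"point-estimate CSV {path} missing columns: "
                         f"{sorted(missing)}")
    return [PointEstimate(str(r.participant_id), float(r.value),
                          float(r.variance), int(r.n_used), str(r.method))
            for r in df.itertuples()]


def write_cohort_manifest(path, spec, truths, files: dict) -> None:
    """JSON provenance record: the full generative spec, per-participant
    truths, and the data files of a simulated cohort."""

    def jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    payload = {
        "spec_type": type(spec).__name__,
        "spec": dataclasses.asdict(spec),
        "truths": [dataclasses.asdict(t) for t in truths],
        "files": {k: str(v) for k, v in files.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=jsonable))


def read_cohort_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# external-deposit adapter


def load_external_tables(root, column_map) -> dict:
    """Adapt an external data deposit into trial collections.

    ``column_map`` is a YAML/JSON file (or an equivalent dict) of the form::

        kinematic:
          file: steps.csv          # path relative to the deposit root
          columns:                 # deposit column -> package column
            subject: participant_id
            pelvis_x: x_pelvis
            ...
        metabolic:
          file: breaths.csv
          columns: {...}
          condition: walking       # constant, if the file has no column

    Returns ``{"kinematic": [KinematicTrial...], "metabolic":
    [MetabolicTrial...]}`` with only the sections present in the map.  The
    deposit's exact schema varies, so nothing is hard-coded: unmapped or
    missing pieces fail with a message listing the files that were found and
    the mapping keys required.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"data path {root} does not exist")
    if isinstance(column_map, (str, Path)):
        column_map = yaml.safe_load(Path(column_map).read_text())
    if not isinstance(column_map, dict) or not (
            {"kinematic", "metabolic"} & set(column_map)):
        found = sorted(p.name for p in root.glob("**/*") if p.is_file())
        raise ValueError(
            "column map must define a 'kinematic' and/or 'metabolic' "
            f"section; deposit contains: {found[:50]}")

    out: dict = {}
    for section, builder, required in (
            ("kinematic", _kinematic_trials_from_frame, KINEMATIC_COLUMNS),
            ("metabolic", _metabolic_trials_from_frame, METABOLIC_COLUMNS)):
        if section not in column_map:
            continue
        cfg = column_map[section]
        fpath = root / cfg["file"]
        if not fpath.exists():
            found = sorted(p.name for p in root.glob("**/*") if p.is_file())
            raise FileNotFoundError(
                f"{section} file {fpath} not found; deposit contains: "
                f"{found[:50]}")
        df = pd.read_csv(fpath)
        rename = cfg.get("columns", {})
        df = df.rename(columns=rename)
        if section == "metabolic" and "condition" not in df.columns:
            if "condition" not in cfg:
                raise ValueError("metabolic mapping needs a 'condition' key "
                                 "or a mapped condition column")
            df["condition"] = cfg["condition"]
        if (section == "kinematic" and "step_index" not in df.columns
                and "participant_id" in df.columns):
            df["step_index"] = df.groupby("participant_id").cumcount()
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(
                f"{section} mapping leaves columns unresolved: "
                f"{sorted(missing)}; map them under "
                f"'{section}: columns:'")
        out[section] = builder(df, fpath)
    return out
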