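"""CSV schemas, validation and stamped writing.

All tables are plain CSV. Files written by the pipeline start with a
comment line recording the config hash and seed; readers skip ``#`` lines.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GazeRecording, InvalidInputError, RawCoPRecording

GAZE_COLUMNS = ["subject_id", "t_s", "gaze_x_deg", "gaze_y_deg", "valid"]
COP_COLUMNS = ["subject_id", "condition", "t_s", "cop_x_cm", "cop_y_cm"]
CLINICAL_COLUMNS = ["subject_id", "group"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_gaze_csv(path) -> dict[str, GazeRecording]:
    df = read_table(path)
    _require_columns(df, GAZE_COLUMNS, path)
    out: dict[str, GazeRecording] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise InvalidInputError(
                f"{path}: timestamps not strictly increasing for subject {sid} "
                f"(around row {grp.index[bad] + 2})"
            )
        dts = np.diff(t)
        rate = 1.0 / float(np.median(dts))
        if np.max(np.abs(dts - 1.0 / rate)) > 0.25 / rate:
            raise InvalidInputError(f"{path}: gaze sampling not uniform for subject {sid}")
        out[str(sid)] = GazeRecording(
            subject_id=str(sid),
            rate=rate,
            gx=grp["gaze_x_deg"].to_numpy(dtype=float),
            gy=grp["gaze_y_deg"].to_numpy(dtype=float),
            valid=grp["valid"].to_numpy().astype(bool),
        )
    return out


def read_cop_csv(path) -> dict[tuple[str, str], RawCoPRecording]:
    df = read_table(path)
    _require_columns(df, COP_COLUMNS, path)
    out: dict[tuple[str, str], RawCoPRecording] = {}
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(
                f"{path}: timestamps not strictly increasing for subject {sid}/{cond}"
            )
        out[(str(sid), str(cond))] = RawCoPRecording(
            subject_id=str(sid),
            condition=str(cond),
            t=t,
            x=grp["cop_x_cm"].to_numpy(dtype=float),
            y=grp["cop_y_cm"].to_numpy(dtype=float),
        )
    return out


def read_clinical_csv(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, CLINICAL_COLUMNS, path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_stamped_csv(df: pd.DataFrame, path, stamp: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def cross_match(
    gaze: dict[str, GazeRecording],
    cop: dict[tuple[str, str], RawCoPRecording],
    clinical: pd.DataFrame,
) -> list[str]:
    """Subjects present in every table with both CoP conditions; others warned."""
    clin_ids = set(clinical["subject_id"])
    all_ids = sorted(clin_ids | set(gaze) | {sid for sid, _ in cop})
    kept = []
    for sid in all_ids:
        missing = []
        if sid not in gaze:
            missing.append("gaze")
        for cond in ("EO", "EC"):
            if (sid, cond) not in cop:
                missing.append(f"CoP/{cond}")
        if sid not in clin_ids:
            missing.append("clinical")
        if missing:
            warnings.warn(f"subject {sid} dropped (missing: {', '.join(missing)})", stacklevel=2)
        else:
            kept.append(sid)
    return kept
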