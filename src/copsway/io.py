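"""Reading and writing the pipeline's plain-text file formats.

Trial files are CSV with header ``time_s,cop_ap_mm,cop_ml_mm``, one file
per trial named ``<subject_id>_<trial_id>.csv``, or a single long-format
file with additional ``subject_id,trial_id`` columns. Subject metadata is
a CSV with columns ``subject_id,group,age_years,therapy,trial_id``. All
floats are written at full precision so that writing and re-reading a
cohort is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTrial, GroundTruth
from .metrics import (
    FEATURE_NAMES,
    CopTrajectory,
    InvalidTrajectoryError,
    extract_features,
)

__all__ = [
    "TRIAL_COLUMNS",
    "METADATA_COLUMNS",
    "FEATURES_COLUMNS",
    "IngestError",
    "write_trial_csv",
    "read_trial_csv",
    "write_cohort",
    "read_trials",
    "features_from_trials",
    "write_features",
    "read_features",
    "write_truth",
]

TRIAL_COLUMNS: tuple[str, ...] = ("time_s", "cop_ap_mm", "cop_ml_mm")
METADATA_COLUMNS: tuple[str, ...] = (
    "subject_id", "group", "age_years", "therapy", "trial_id")
FEATURES_COLUMNS: tuple[str, ...] = (
    "subject_id", "trial_id", "fs_hz", "duration_s", *FEATURE_NAMES)

_FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


class IngestError(ValueError):
    """A file failed schema validation; the message names file and line."""


def write_trial_csv(traj: CopTrajectory, path) -> None:
    """Write one trial's COP time series as CSV."""
    frame = pd.DataFrame({
        "time_s": traj.time, "cop_ap_mm": traj.ap, "cop_ml_mm": traj.ml})
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _numeric_or_raise(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.index[values.isna() & frame[column].notna()]
    if len(bad) or values.isna().any():
        row = int((values.isna()).idxmax())
        # +2: header line plus 1-based numbering
        raise IngestError(
            f"{path}: line {row + 2}: non-numeric or missing value in "
            f"column {column!r}")
    return values.to_numpy(float)


def _frame_to_trajectory(frame: pd.DataFrame, path) -> CopTrajectory:
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise IngestError(f"{path}: missing columns {sorted(missing)}")
    cols = {c: _numeric_or_raise(frame, c, path) for c in TRIAL_COLUMNS}
    try:
        return CopTrajectory(
            time=cols["time_s"], ap=cols["cop_ap_mm"], ml=cols["cop_ml_mm"])
    except InvalidTrajectoryError as exc:
        raise IngestError(f"{path}: {exc}") from exc


def read_trial_csv(path) -> CopTrajectory:
    """Read and validate one per-trial COP CSV."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise IngestError(f"{path}: unreadable CSV ({exc})") from exc
    return _frame_to_trajectory(frame, path)


def _read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise IngestError(f"{path}: metadata missing columns "
                          f"{sorted(missing)}")
    return meta


def write_cohort(trials: Sequence[CohortTrial], out_dir) -> Path:
    """Write per-trial CSVs plus ``metadata.csv`` into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for trial in trials:
        name = f"{trial.subject_id}_{trial.trial_id}.csv"
        write_trial_csv(trial.trajectory, out_dir / name)
        meta_rows.append({
            "subject_id": trial.subject_id,
            "group": trial.group,
            "age_years": trial.age_years,
            "therapy": trial.therapy,
            "trial_id": trial.trial_id,
        })
    meta = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    meta.to_csv(out_dir / "metadata.csv", index=False,
                float_format=_FLOAT_FORMAT)
    return out_dir


def _trials_from_long(frame: pd.DataFrame, path) -> list[CohortTrial]:
    for col in ("subject_id", "trial_id"):
        if col not in frame.columns:
            raise IngestError(
                f"{path}: long-format file needs a {col!r} column")
    trials = []
    for (sid, tid), part in frame.groupby(
            ["subject_id", "trial_id"], sort=True):
        traj = _frame_to_trajectory(part.reset_index(drop=True), path)
        trials.append(CohortTrial(
            subject_id=str(sid), trial_id=int(tid), trajectory=traj))
    return trials


def read_trials(path, metadata_path=None) -> list[CohortTrial]:
    """Load trials from a directory of per-trial CSVs or a long-format file.

    A directory is expected to contain ``<subject_id>_<trial_id>.csv``
    files and (optionally) ``metadata.csv``; a single file is parsed as
    long format. When metadata is available (explicit ``metadata_path``
    or the directory's ``metadata.csv``) it is joined on
    ``(subject_id, trial_id)``; otherwise the metadata fields are None.
    """
    path = Path(path)
    if path.is_dir():
        meta_file = (Path(metadata_path) if metadata_path
                     else path / "metadata.csv")
        meta = _read_metadata(meta_file) if meta_file.exists() else None
        if meta is not None:
            trials = []
            for row in meta.itertuples(index=False):
                trial_path = path / f"{row.subject_id}_{row.trial_id}.csv"
                if not trial_path.exists():
                    raise IngestError(f"{trial_path}: listed in metadata "
                                      "but file not found")
                trials.append(CohortTrial(
                    subject_id=str(row.subject_id),
                    trial_id=int(row.trial_id),
                    trajectory=read_trial_csv(trial_path),
                    group=str(row.group),
                    age_years=float(row.age_years),
                    therapy=int(row.therapy),
                ))
            return trials
        files = sorted(path.glob("*.csv"))
        if not files:
            raise IngestError(f"{path}: no trial CSVs found")
        trials = []
        for file in files:
            stem = file.stem
            sid, _, tid = stem.rpartition("_")
            if not sid or not tid.isdigit():
                raise IngestError(
                    f"{file}: cannot parse '<subject_id>_<trial_id>' "
                    "from filename")
            trials.append(CohortTrial(
                subject_id=sid, trial_id=int(tid),
                trajectory=read_trial_csv(file)))
        return trials

    if not path.exists():
        raise IngestError(f"{path}: not found")
    frame = pd.read_csv(path, float_precision="round_trip")
    trials = _trials_from_long(frame, path)
    if metadata_path is not None:
        meta = _read_metadata(metadata_path).set_index(
            ["subject_id", "trial_id"])
        joined = []
        for t in trials:
            try:
                row = meta.loc[(t.subject_id, t.trial_id)]
            except KeyError as exc:
                raise IngestError(
                    f"{metadata_path}: no metadata for trial "
                    f"({t.subject_id}, {t.trial_id})") from exc
            joined.append(CohortTrial(
                subject_id=t.subject_id, trial_id=t.trial_id,
                trajectory=t.trajectory, group=str(row["group"]),
                age_years=float(row["age_years"]),
                therapy=int(row["therapy"])))
        return joined
    return trials


def features_from_trials(
    trials: Iterable[CohortTrial],
    *,
    lowpass_hz: float | None = None,
    freq_component_form: str = "prieto",
) -> pd.DataFrame:
    """Extract the 16 features for every trial into the features table."""
    rows = []
    for trial in trials:
        feats = extract_features(
            trial.trajectory, lowpass_hz=lowpass_hz,
            freq_component_form=freq_component_form)
        rows.append({
            "subject_id": trial.subject_id,
            "trial_id": trial.trial_id,
            "fs_hz": feats.fs_hz,
            "duration_s": feats.duration_s,
            **feats.as_dict(),
        })
    return pd.DataFrame(rows, columns=list(FEATURES_COLUMNS))


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_features(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(FEATURES_COLUMNS) - set(frame.columns)
    if missing:
        raise IngestError(f"{path}: features file missing columns "
                          f"{sorted(missing)}")
    return frame


def join_features_metadata(
    features: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Trial-level cohort table: features joined to subject metadata."""
    meta = metadata[list(METADATA_COLUMNS)]
    joined = features.merge(
        meta, on=["subject_id", "trial_id"], how="left", validate="1:1")
    if joined["group"].isna().any():
        orphans = joined.loc[joined["group"].isna(),
                             ["subject_id", "trial_id"]]
        raise IngestError(
            "trials without metadata: "
            + ", ".join(f"({r.subject_id}, {r.trial_id})"
                        for r in orphans.itertuples(index=False)))
    return joined


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(
        json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
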