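"""Plain-text readers/writers for trials, datasets and feature matrices."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features_classic import FeatureMatrix
from .synth_emg import DEFAULT_PHASE_NAMES, EmgRecording

SIDECAR_NAME = "dataset.yaml"
_TRIAL_RE = re.compile(r"subject(\d+)_trial(\d+)\.csv$")


def trial_filename(subject_id: int, trial_id: int) -> str:
    return f"subject{subject_id:03d}_trial{trial_id:03d}.csv"


def write_trial(rec: EmgRecording, directory: str | Path) -> Path:
    """One CSV per trial: channel columns plus an integer label column."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / trial_filename(rec.subject_id, rec.trial_id)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
    df["label"] = rec.labels
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def write_sidecar(
    directory: str | Path,
    fs: float,
    channel_names: list[str],
    phase_names: list[str] | tuple[str, ...] = DEFAULT_PHASE_NAMES,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / SIDECAR_NAME
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "fs": float(fs),
                "channel_names": list(channel_names),
                "phase_names": list(phase_names),
            },
            fh,
            sort_keys=False,
        )
    return path


def write_dataset(recordings: list[EmgRecording], directory: str | Path) -> Path:
    """Write every trial plus the YAML sidecar describing the dataset."""
    if not recordings:
        raise ValueError("no recordings to write")
    directory = Path(directory)
    for rec in recordings:
        write_trial(rec, directory)
    first = recordings[0]
    write_sidecar(directory, first.fs, first.channel_names)
    return directory


def read_sidecar(directory: str | Path) -> dict:
    with open(Path(directory) / SIDECAR_NAME) as fh:
        return yaml.safe_load(fh)


def read_trial(path: str | Path, fs: float) -> EmgRecording:
    path = Path(path)
    m = _TRIAL_RE.search(path.name)
    if not m:
        raise ValueError(f"trial filename {path.name!r} does not match the naming scheme")
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path} has no 'label' column")
    channels = [c for c in df.columns if c != "label"]
    return EmgRecording(
        samples=df[channels].to_numpy().T,
        fs=fs,
        labels=df["label"].to_numpy(),
        trial_id=int(m.group(2)),
        subject_id=int(m.group(1)),
        channel_names=channels,
    )


def read_dataset(directory: str | Path, subject_id: int | None = None) -> list[EmgRecording]:
    """Load all trials (optionally one subject) from a dataset directory."""
    directory = Path(directory)
    meta = read_sidecar(directory)
    recs = []
    for path in sorted(directory.glob("subject*_trial*.csv")):
        rec = read_trial(path, fs=meta["fs"])
        if subject_id is None or rec.subject_id == subject_id:
            recs.append(rec)
    if not recs:
        raise FileNotFoundError(f"no matching trial files under {directory}")
    return recs


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    """Feature matrix as CSV: named feature columns plus label/trial columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df["label"] = fm.labels
    df["trial_id"] = fm.trial_ids
    df["subject_id"] = fm.subject_id
    df["feature_set"] = fm.name
    df.to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    meta_cols = ["label", "trial_id", "subject_id", "feature_set"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing columns {missing}")
    feature_cols = [c for c in df.columns if c not in meta_cols]
    return FeatureMatrix(
        values=df[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
        labels=df["label"].to_numpy(),
        trial_ids=df["trial_id"].to_numpy(),
        subject_id=int(df["subject_id"].iloc[0]),
        name=str(df["feature_set"].iloc[0]),
    )


def append_quality_row(path: str | Path, report) -> Path:
    """Append one QualityReport row to a results table (creating it if needed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    row = pd.DataFrame(
        [
            {
                "subject": report.subject_id,
                "feature_set": report.feature_set_name,
                "SI": report.si,
                "MSA": report.msa,
                "K": report.K,
                "D": report.D,
            }
        ]
    )
    row.to_csv(path, mode="a", header=not path.exists(), index=False)
    return path
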