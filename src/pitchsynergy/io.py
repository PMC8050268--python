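"""Readers and writers: long-format tensor CSV, model and result files.

The tensor travels as a long-format CSV with columns
``subject, trial, effort, muscle, frame, value`` (trials and frames
1-based in files, 0-based in memory) plus a JSON sidecar carrying the
schema version, frame rate, effort labels and ball speeds. Writing then
reading reproduces the tensor and metadata exactly; an incomplete grid
is rejected naming the first missing (muscle, frame, trial) cell.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EMGTensor
from .decompose import CPModel
from .exceptions import IncompleteGridError, SchemaVersionError

SCHEMA_VERSION = "1"

__all__ = [
    "write_tensor_csv",
    "read_tensor_csv",
    "write_cp_model",
    "read_cp_model",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_tensor_csv(tensor: EMGTensor, path: str | Path) -> Path:
    """Write the tensor and its JSON metadata sidecar; returns the CSV path."""
    path = Path(path)
    S, T, K = tensor.X.shape
    muscle_idx, frame_idx, trial_idx = np.meshgrid(
        np.arange(S), np.arange(T), np.arange(K), indexing="ij")
    df = pd.DataFrame({
        "subject": tensor.subject_id,
        "trial": trial_idx.ravel() + 1,
        "effort": tensor.effort_labels[trial_idx.ravel()],
        "muscle": np.asarray(tensor.muscle_labels)[muscle_idx.ravel()],
        "frame": frame_idx.ravel() + 1,
        "value": tensor.X.ravel(),
    })
    df.to_csv(path, index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": tensor.subject_id,
        "muscle_labels": list(tensor.muscle_labels),
        "effort_labels": [int(e) for e in tensor.effort_labels],
        "ball_speeds": (None if tensor.ball_speeds is None
                        else [float(v) for v in tensor.ball_speeds]),
        "frame_rate_hz": tensor.frame_rate_hz,
        "n_frames": T,
        "release_frame": T,  # 1-based: release is the last frame
        "normalized": bool(tensor.normalized),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_tensor_csv(path: str | Path) -> EMGTensor:
    """Read a long-format tensor CSV written by :func:`write_tensor_csv`."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    meta = None
    if sidecar_file.exists():
        meta = json.loads(sidecar_file.read_text())
        version = str(meta.get("schema_version"))
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"unsupported tensor schema version {version!r}; "
                f"this reader understands version {SCHEMA_VERSION!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject", "trial", "effort", "muscle", "frame", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise IncompleteGridError(f"missing columns: {sorted(missing_cols)}")

    muscles = (meta["muscle_labels"] if meta is not None
               else list(pd.unique(df["muscle"])))
    trials = np.sort(df["trial"].unique())
    frames = np.arange(1, df["frame"].max() + 1)
    S, T, K = len(muscles), len(frames), len(trials)
    if df.duplicated(["muscle", "frame", "trial"]).any():
        raise IncompleteGridError("duplicated (muscle, frame, trial) rows")
    muscle_idx = {m: i for i, m in enumerate(muscles)}
    trial_idx = {int(k): i for i, k in enumerate(trials)}
    unknown = set(df["muscle"]) - set(muscles)
    if unknown:
        raise IncompleteGridError(f"unexpected muscle labels {sorted(unknown)}")
    X = np.full((S, T, K), np.nan)
    X[df["muscle"].map(muscle_idx).to_numpy(),
      df["frame"].to_numpy() - 1,
      df["trial"].map(trial_idx).to_numpy()] = df["value"].to_numpy()
    if np.isnan(X).any():
        i, j, k = np.argwhere(np.isnan(X))[0]
        raise IncompleteGridError(
            f"grid incomplete: first missing cell is "
            f"(muscle={muscles[i]!r}, frame={frames[j]}, "
            f"trial={trials[k]})")

    effort_by_trial = df.drop_duplicates("trial").set_index("trial")["effort"]
    effort = effort_by_trial.loc[trials].to_numpy()
    ball_speeds = None
    frame_rate = 200.0
    subject = str(df["subject"].iloc[0])
    normalized = False
    if meta is not None:
        if meta.get("ball_speeds") is not None:
            ball_speeds = np.asarray(meta["ball_speeds"], dtype=float)
        frame_rate = float(meta.get("frame_rate_hz", frame_rate))
        subject = meta.get("subject_id", subject)
        normalized = bool(meta.get("normalized", False))
    return EMGTensor(
        X=X, muscle_labels=tuple(muscles), effort_labels=effort,
        ball_speeds=ball_speeds, subject_id=subject,
        frame_rate_hz=frame_rate, normalized=normalized)


def write_cp_model(model: CPModel, out_dir: str | Path,
                   muscle_labels: tuple[str, ...] | None = None) -> Path:
    """Serialize a CP model: JSON metadata plus three labeled factor CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    S, T, K = model.shape
    comp_cols = [f"component_{r + 1}" for r in range(model.rank)]
    rows = (list(muscle_labels) if muscle_labels is not None
            else [f"M{i + 1}" for i in range(S)])
    pd.DataFrame(model.spatial, index=pd.Index(rows, name="muscle"),
                 columns=comp_cols).to_csv(out / "spatial.csv")
    pd.DataFrame(model.temporal, index=pd.Index(np.arange(1, T + 1), name="frame"),
                 columns=comp_cols).to_csv(out / "temporal.csv")
    pd.DataFrame(model.trial, index=pd.Index(np.arange(1, K + 1), name="trial"),
                 columns=comp_cols).to_csv(out / "trial.csv")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "lambdas": [float(v) for v in model.lambdas],
        "rank": model.rank,
        "shape": list(model.shape),
    }
    if model.diagnostics is not None:
        d = dataclasses.asdict(model.diagnostics)
        d["objective_history"] = [float(v) for v in d["objective_history"]]
        meta["diagnostics"] = d
    (out / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_cp_model(model_dir: str | Path) -> CPModel:
    out = Path(model_dir)
    meta = json.loads((out / "model.json").read_text())
    if str(meta.get("schema_version")) != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported model schema version {meta.get('schema_version')!r}")
    load = lambda name: pd.read_csv(out / name, index_col=0).to_numpy()
    return CPModel(
        spatial=load("spatial.csv"),
        temporal=load("temporal.csv"),
        trial=load("trial.csv"),
        lambdas=np.asarray(meta["lambdas"], dtype=float),
    )
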