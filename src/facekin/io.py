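"""Readers, writers and pipeline configuration.

Interchange formats are plain text: one CSV per recording (``frame``, the
44 blendshape columns in the package's fixed order, then the 68 x 3
landmark coordinate columns ``lm01_x`` ... ``lm68_z``), a participants CSV,
a manifest CSV, JSON summaries, and a YAML pipeline configuration validated
against a pydantic schema before any stage runs.  Frame and repetition
indices are 1-based in all files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .blendshapes import (
    ANALYSIS_BLENDSHAPES,
    LANDMARK_COLUMNS,
    N_BLENDSHAPES,
    N_LANDMARKS,
)
from .synthetic import Dataset
from .types import DataError, ParticipantMeta, Recording

RECORDING_COLUMNS = ("frame",) + ANALYSIS_BLENDSHAPES + LANDMARK_COLUMNS


class FormatError(DataError):
    """File does not match the documented layout."""


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write one recording to CSV in the documented column layout."""
    path = Path(path)
    n = recording.n_frames
    frame = np.arange(1, n + 1)
    data = np.column_stack([
        frame, recording.blendshapes,
        recording.landmarks.reshape(n, N_LANDMARKS * 3)])
    df = pd.DataFrame(data, columns=list(RECORDING_COLUMNS))
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_recording(path: str | Path, participant_id: str = "",
                   condition: str = "cued", emotion: str = "anger",
                   repetition: int = 1,
                   frame_rate: float = 60.0) -> Recording:
    """Read and validate a recording CSV.

    The file must carry exactly the documented columns: ``frame``, the 44
    analysis blendshapes, and the 204 landmark coordinates.  Activations
    outside [0, 1] raise a validation error naming the offending row
    (1-based frame index).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = list(RECORDING_COLUMNS)
    if list(df.columns) != expected:
        n_bs = sum(c in ANALYSIS_BLENDSHAPES for c in df.columns)
        raise FormatError(
            f"{path.name}: expected {len(expected)} columns "
            f"(frame, {N_BLENDSHAPES} blendshapes, {N_LANDMARKS * 3} "
            f"landmark coordinates), found {len(df.columns)} with "
            f"{n_bs} blendshape columns")
    activations = df[list(ANALYSIS_BLENDSHAPES)].to_numpy(dtype=float)
    bad = np.argwhere((activations < 0) | (activations > 1))
    if bad.size:
        row, col = bad[0]
        raise DataError(
            f"{path.name}: activation {activations[row, col]:g} outside "
            f"[0, 1] at row {int(df['frame'].iloc[row])}, column "
            f"{ANALYSIS_BLENDSHAPES[col]}")
    landmarks = df[list(LANDMARK_COLUMNS)].to_numpy(dtype=float).reshape(
        len(df), N_LANDMARKS, 3)
    return Recording(participant_id=participant_id, condition=condition,
                     emotion=emotion, repetition=repetition,
                     blendshapes=activations, landmarks=landmarks,
                     frame_rate=frame_rate)


def participants_frame(participants: list[ParticipantMeta]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": p.participant_id, "group": p.group, "tas": p.tas,
        "aq": p.aq, "iq": p.iq, "age": p.age, "sex": p.sex,
    } for p in participants])


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  max_recordings: int | None = None) -> Path:
    """Write a generated dataset: per-recording CSVs under ``recordings/``,
    ``participants.csv``, ``manifest.csv`` and a config echo.

    ``max_recordings`` caps the number of recording files written (the
    manifest always covers the full design), useful at the full study scale
    where materialising everything is rarely wanted.
    """
    out_dir = Path(out_dir)
    rec_dir = out_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    participants_frame(dataset.participants).to_csv(
        out_dir / "participants.csv", index=False)
    manifest = dataset.manifest.copy()
    filenames = [
        f"{r.participant_id}_{r.condition}_{r.emotion}_rep{r.repetition:02d}.csv"
        for r in manifest.itertuples(index=False)]
    manifest["filename"] = filenames
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    config = dataset.config
    echo = {k: v for k, v in vars(config).items()
            if k not in ("effects", "trait_params")}
    echo["effects"] = [vars(e) | {"unit_ids": list(e.unit_ids),
                                  "time_window": list(e.time_window)}
                       for e in config.effects]
    echo["trait_params"] = {g: {k: list(v) for k, v in d.items()}
                            for g, d in config.trait_params.items()}
    echo["emotions"] = list(config.emotions)
    echo["conditions"] = list(config.conditions)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(echo))
    n_written = 0
    for row, filename in zip(manifest.itertuples(index=False), filenames):
        if max_recordings is not None and n_written >= max_recordings:
            break
        rec = dataset.get_recording(row.participant_id, row.condition,
                                    row.emotion, row.repetition)
        write_recording(rec, rec_dir / filename)
        n_written += 1
    return out_dir


def write_jerk(jerk_values: np.ndarray, path: str | Path) -> Path:
    """Write a jerk series as CSV (frame x 68 landmarks, 1-based frames
    counted from the first valid jerk frame)."""
    path = Path(path)
    df = pd.DataFrame(jerk_values,
                      columns=[f"lm{i:02d}" for i in range(1, N_LANDMARKS + 1)])
    df.insert(0, "frame", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


class MassUnivariateOptions(BaseModel):
    n_permutations: int = Field(default=1000, ge=100)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    pooling: str = "max"
    timing_mode: str = "time_averaged"
    engine: str = "auto"

    @field_validator("pooling")
    @classmethod
    def _check_pooling(cls, v: str) -> str:
        if v not in ("max", "per_unit"):
            raise ValueError(f"unknown pooling {v!r}")
        return v


class SelectionOptions(BaseModel):
    n_iterations: int = Field(default=50, ge=10)
    n_estimators: int = Field(default=100, ge=10)
    importance: str = "permutation"
    alpha_entry: float = Field(default=0.05, gt=0, lt=1)


class SimulationOptions(BaseModel):
    n_per_group: int = Field(default=4, ge=1)
    n_repetitions: int = Field(default=4, ge=2)
    frames_cued: int = Field(default=54, ge=10)
    frames_spoken_mean: int = Field(default=40, ge=10)
    frames_spoken_jitter: int = Field(default=4, ge=0)
    subject_sd: float = Field(default=0.04, ge=0)
    repetition_sd: float = Field(default=0.01, ge=0)
    residual_sd: float = Field(default=0.05, ge=0)


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (YAML-loadable)."""

    out_dir: str
    seed: int = 0
    measures: list[str] = ["activation", "jerk"]
    conditions: list[str] = ["cued", "spoken"]
    emotions: list[str] = ["anger", "happiness", "sadness"]
    peak_index: int = Field(default=270, ge=1)
    simulation: SimulationOptions = SimulationOptions()
    mass_univariate: MassUnivariateOptions = MassUnivariateOptions()
    selection: SelectionOptions = SelectionOptions()

    @field_validator("measures")
    @classmethod
    def _check_measures(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"activation", "jerk"}
        if bad:
            raise ValueError(f"unknown measures: {sorted(bad)}")
        return v


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration; any schema
    violation raises before a stage runs."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: pipeline config must be a mapping")
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_json(obj: object, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj: object):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
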