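"""Configuration files, record/model serialization, and run manifests.

All tabular artifacts are CSV (full float precision, UTF-8, '.' decimal);
configs are YAML with strict key checking; model weights and manifests are
JSON.  Every output embeds the seed needed to reproduce it bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amp import AMPConfig, AMPModel
from .control import ControllerConfig
from .predict import Dataset, MLPModel, TrainConfig
from .simulate import (
    GeneratorParams,
    PulseLog,
    SonicationProtocol,
    SonicationRecord,
    SubjectModel,
)
from .spectral import AEFrame, EVENT_THRESHOLD_DB

__all__ = [
    "ConfigError",
    "FormatError",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "record_to_dataframe",
    "save_record",
    "load_record",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


class FormatError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Top-level experiment description."""

    protocol: SonicationProtocol = field(default_factory=SonicationProtocol)
    subjects: list[SubjectModel] = field(default_factory=lambda: [SubjectModel()])
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    controllers: list[ControllerConfig] = field(
        default_factory=lambda: [ControllerConfig()]
    )
    predictor: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    output_dir: str = "results"


_BLOCK_TYPES = {
    "protocol": SonicationProtocol,
    "generator": GeneratorParams,
    "predictor": TrainConfig,
}
_LIST_BLOCK_TYPES = {"subjects": SubjectModel, "controllers": ControllerConfig}
_SCALAR_KEYS = {"seed", "output_dir"}


def _build_block(cls: type, data: dict, path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        obj = cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if isinstance(obj, ControllerConfig) and obj.p_min_mpa > obj.p_max_mpa:
        raise ConfigError(f"{path}: p_min_mpa > p_max_mpa")
    return obj


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Parse and validate a YAML experiment config (unknown keys rejected)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    known = set(_BLOCK_TYPES) | set(_LIST_BLOCK_TYPES) | _SCALAR_KEYS
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, cls in _BLOCK_TYPES.items():
        if key in raw:
            kwargs[key] = _build_block(cls, raw[key], key)
    for key, cls in _LIST_BLOCK_TYPES.items():
        if key in raw:
            if not isinstance(raw[key], list):
                raise ConfigError(f"{key}: expected a list of mappings")
            kwargs[key] = [
                _build_block(cls, item, f"{key}[{i}]")
                for i, item in enumerate(raw[key])
            ]
    for key in _SCALAR_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    return ExperimentConfig(**kwargs)


def save_config(config: ExperimentConfig, path: Union[str, Path]) -> None:
    data = {
        "protocol": asdict(config.protocol),
        "subjects": [asdict(s) for s in config.subjects],
        "generator": asdict(config.generator),
        "controllers": [
            {k: v for k, v in asdict(c).items()} for c in config.controllers
        ],
        "predictor": asdict(config.predictor),
        "seed": config.seed,
        "output_dir": config.output_dir,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Sonication records

_H_COLS = [f"h{n}_db" for n in range(2, 9)]
_UH_COLS = [f"uh{k}_db" for k in range(1, 8)]
RECORD_COLUMNS = (
    ["pulse_index", "time_s", "pressure_mpa"]
    + _H_COLS
    + _UH_COLS
    + ["h4_track_db", "broadband_db", "is_event", "phase", "prediction", "safety_action"]
)


def record_to_dataframe(record: SonicationRecord) -> pd.DataFrame:
    rows = []
    for log in record.pulses:
        f = log.frame
        row: dict[str, Any] = {
            "pulse_index": f.pulse_index,
            "time_s": f.time_s,
            "pressure_mpa": f.pressure_mpa,
        }
        for i, n in enumerate(range(2, 9)):
            row[f"h{n}_db"] = f.harmonic_db[i]
        for i, k in enumerate(range(1, 8)):
            row[f"uh{k}_db"] = f.ultraharmonic_db[i]
        row.update(
            h4_track_db=f.h4_db,
            broadband_db=f.broadband_db,
            is_event=int(f.is_event),
            phase=log.phase,
            prediction=log.prediction,
            safety_action=log.safety_action,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def save_record(
    record: SonicationRecord, path: Union[str, Path], manifest: bool = True
) -> Path:
    """Write a record as CSV (plus a JSON sidecar manifest)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record_to_dataframe(record).to_csv(path, index=False, float_format="%.17g")
    if manifest:
        side = {
            "package_version": __version__,
            "seed": record.seed,
            "controller_label": record.controller_label,
            "valid": record.valid,
            "ktrans": record.ktrans,
            "protocol": asdict(record.protocol),
            "subject": asdict(record.subject),
        }
        _manifest_path(path).write_text(json.dumps(side, indent=1))
    return path


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".manifest.json")


def load_record(path: Union[str, Path]) -> SonicationRecord:
    """Read a record CSV (and its manifest sidecar when present)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"record file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty record file: {path}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown column(s) {extra} in {path}", RuntimeWarning)

    protocol = SonicationProtocol()
    subject = SubjectModel()
    seed, label, valid, ktrans = 0, "unknown", True, float("nan")
    mpath = _manifest_path(path)
    if mpath.exists():
        side = json.loads(mpath.read_text())
        protocol = SonicationProtocol(**side["protocol"])
        subject = SubjectModel(**side["subject"])
        seed = side["seed"]
        label = side["controller_label"]
        valid = side["valid"]
        ktrans = side["ktrans"]

    record = SonicationRecord(
        protocol=protocol, subject=subject, controller_label=label,
        seed=seed, valid=valid, ktrans=ktrans,
    )
    for _, row in df.iterrows():
        bb = float(row["broadband_db"])
        frame = AEFrame(
            pulse_index=int(row["pulse_index"]),
            time_s=float(row["time_s"]),
            pressure_mpa=float(row["pressure_mpa"]),
            harmonic_db=tuple(float(row[c]) for c in _H_COLS),
            ultraharmonic_db=tuple(float(row[c]) for c in _UH_COLS),
            h4_db=float(row["h4_track_db"]),
            broadband_db=bb,
            is_event=bb >= EVENT_THRESHOLD_DB,
        )
        record.pulses.append(
            PulseLog(
                frame=frame,
                phase=str(row["phase"]),
                prediction=float(row["prediction"]),
                safety_action=str(row["safety_action"]),
            )
        )
    return record


# ---------------------------------------------------------------------------
# Datasets

def save_dataset(dataset: Dataset, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    df["label"] = dataset.y
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_dataset(path: Union[str, Path]) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty dataset file: {path}") from exc
    if "label" not in df.columns:
        raise FormatError(f"missing column(s) ['label'] in {path}")
    names = tuple(c for c in df.columns if c != "label")
    return Dataset(
        df[list(names)].to_numpy(float), df["label"].to_numpy(), names,
        {"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Models

def save_model(model: Union[MLPModel, AMPModel], path: Union[str, Path]) -> Path:
    """Portable JSON weight file (shapes, weights, scaler, threshold)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, MLPModel):
        data = {
            "kind": "mlp",
            "package_version": __version__,
            "W1": model.W1.tolist(),
            "b1": model.b1.tolist(),
            "w2": model.w2.tolist(),
            "b2": model.b2,
            "x_mean": model.x_mean.tolist(),
            "x_sd": model.x_sd.tolist(),
            "feature_names": list(model.feature_names),
            "threshold": model.threshold,
        }
    elif isinstance(model, AMPModel):
        data = {
            "kind": "amp",
            "package_version": __version__,
            "config": asdict(model.config),
            "params": {k: v.tolist() for k, v in model.params.items()},
            "x_mean": model.x_mean.tolist(),
            "x_sd": model.x_sd.tolist(),
            "feature_names": list(model.feature_names),
            "threshold": model.threshold,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(json.dumps(data, indent=1))
    return path


def load_model(path: Union[str, Path]) -> Union[MLPModel, AMPModel]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    data = json.loads(path.read_text())
    kind = data.get("kind")
    if kind == "mlp":
        return MLPModel(
            W1=np.asarray(data["W1"], dtype=float),
            b1=np.asarray(data["b1"], dtype=float),
            w2=np.asarray(data["w2"], dtype=float),
            b2=float(data["b2"]),
            x_mean=np.asarray(data["x_mean"], dtype=float),
            x_sd=np.asarray(data["x_sd"], dtype=float),
            feature_names=tuple(data["feature_names"]),
            threshold=float(data["threshold"]),
        )
    if kind == "amp":
        cfg = data["config"]
        cfg["frequency_dims"] = tuple(cfg["frequency_dims"])
        return AMPModel(
            params={k: np.asarray(v, dtype=float) for k, v in data["params"].items()},
            config=AMPConfig(**cfg),
            x_mean=np.asarray(data["x_mean"], dtype=float),
            x_sd=np.asarray(data["x_sd"], dtype=float),
            feature_names=tuple(data["feature_names"]),
            threshold=float(data["threshold"]),
        )
    raise FormatError(f"unknown model kind {kind!r} in {path}")


def write_manifest(
    path: Union[str, Path],
    seed: int,
    config: Optional[ExperimentConfig] = None,
    files: Optional[Sequence[str]] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Run manifest: version, seed, config echo, output file list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data: dict[str, Any] = {
        "package_version": __version__,
        "seed": int(seed),
    }
    if config is not None:
        data["config"] = json.loads(
            json.dumps(dataclasses.asdict(config), default=str)
        )
    if files is not None:
        data["files"] = list(files)
    if extra:
        data.update(extra)
    path.write_text(json.dumps(data, indent=1))
    return path
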