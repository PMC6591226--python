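"""File I/O and configuration: CSV recordings, sidecar JSON metadata,
YAML regime/pipeline configuration with strict key checking, and a
master-seed splitting rule shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .miles import (DEFAULT_LAMBDA_GRID, DEFAULT_POOL_CAP, DEFAULT_SIGMA_GRID)
from .segment import PPGRecording
from .synth import BeatShapeParams, CohortParams, GroundTruth, SynthRecording

__all__ = [
    "PipelineConfig",
    "load_regime",
    "read_recording_csv",
    "write_recording_csv",
    "derive_stage_seed",
    "config_hash",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the cohort parameters.

    The inner loop of hyperparameter tuning runs ``inner_splits`` seeded
    subject-level splits at ``train_frac`` training fraction (set 0.3 to
    honour the literal 70% test / 30% train reading of the split).
    """

    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    pool_cap: int = DEFAULT_POOL_CAP
    inner_splits: int = 68
    train_frac: float = 0.7
    n_boot: int = 2000
    seed: int = 1729

    def validate(self) -> None:
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.inner_splits < 1 or self.n_boot < 1 or self.pool_cap < 1:
            raise ValueError("counts must be positive")
        if any(s <= 0 for s in self.sigma_grid) or any(l <= 0 for l in self.lambda_grid):
            raise ValueError("grid values must be positive")


def _build_dataclass(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "beat_shape":
            v = _build_dataclass(BeatShapeParams, dict(v), "beat_shape")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_regime(name_or_path: str) -> tuple[CohortParams, CohortParams, int]:
    """Load a cohort regime: the packaged ``paper_regime``/``null_regime``
    by name, or any YAML file by path.  Returns (healthy, ohcm, seed)."""
    if name_or_path in ("paper_regime", "null_regime"):
        text = (resources.files("ppgmiles.config") / f"{name_or_path}.yaml").read_text()
    else:
        text = Path(name_or_path).read_text()
    data = yaml.safe_load(text)
    unknown = set(data) - {"seed", "healthy", "ohcm"}
    if unknown:
        raise ValueError(f"unknown top-level regime keys: {sorted(unknown)}")
    healthy = _build_dataclass(CohortParams, dict(data["healthy"]), "healthy")
    ohcm = _build_dataclass(CohortParams, dict(data["ohcm"]), "ohcm")
    healthy.validate()
    ohcm.validate()
    return healthy, ohcm, int(data.get("seed", 0))


def config_hash(obj) -> str:
    """Short deterministic hash of any (nested) dataclass/dict config."""
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, np.generic):
            return o.item()
        return o
    blob = json.dumps(enc(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of ``"{master}:{stage}"``
    reduced mod 2**31.  One master seed fans out to every stage."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# recordings on disk
# ---------------------------------------------------------------------------


def write_recording_csv(rec: PPGRecording | SynthRecording, path: Path,
                        ground_truth: Optional[GroundTruth] = None,
                        seed: Optional[int] = None) -> None:
    """Write ``t_seconds,amplitude`` CSV plus a ``.meta.json`` sidecar
    (and ``.truth.json`` when ground truth is given)."""
    path = Path(path)
    t = np.arange(len(rec.samples)) / rec.sampling_rate
    pd.DataFrame({"t_seconds": t, "amplitude": rec.samples}).to_csv(path, index=False)
    meta = {
        "subject_id": rec.subject_id, "recording_id": rec.recording_id,
        "label": rec.label, "sampling_rate_hz": rec.sampling_rate,
        "seed": seed if seed is not None else getattr(rec, "seed", None),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    if ground_truth is not None:
        truth = {
            "beat_onset_times": ground_truth.beat_onset_times.tolist(),
            "peak_times": ground_truth.peak_times.tolist(),
            "notch_times": ground_truth.notch_times.tolist(),
        }
        path.with_suffix(".truth.json").write_text(json.dumps(truth))


def read_recording_csv(path: Path, metadata: Optional[dict] = None) -> PPGRecording:
    """Read a recording written by :func:`write_recording_csv` (or any
    ``t_seconds,amplitude`` / ``sample,amplitude`` CSV).

    Validation failures (malformed header, NaN amplitudes, non-monotone
    time) raise ``ValueError`` naming the offending row; the sampling
    rate comes from the time column or the sidecar metadata.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] not in (["t_seconds", "amplitude"], ["sample", "amplitude"]):
        raise ValueError(
            f"{path.name}: header must be 't_seconds,amplitude' or "
            f"'sample,amplitude', got {cols}")
    if metadata is None:
        sidecar = path.with_suffix(".meta.json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    amp = df["amplitude"].to_numpy(dtype=float)
    nan_rows = np.flatnonzero(np.isnan(amp))
    if len(nan_rows):
        raise ValueError(f"{path.name}: NaN amplitude at row {int(nan_rows[0]) + 1}")
    if cols[0] == "t_seconds":
        t = df["t_seconds"].to_numpy(dtype=float)
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if len(bad):
            raise ValueError(f"{path.name}: non-monotone time at row {int(bad[0]) + 2}")
        fs = float(metadata.get("sampling_rate_hz", 1.0 / np.median(dt)))
    else:
        fs = metadata.get("sampling_rate_hz")
        if fs is None:
            raise ValueError(f"{path.name}: 'sample' format needs "
                             "sampling_rate_hz in the sidecar metadata")
    rec = PPGRecording(
        samples=amp, sampling_rate=float(fs),
        subject_id=str(metadata.get("subject_id", "unknown")),
        recording_id=str(metadata.get("recording_id", path.stem)),
        label=str(metadata.get("label", "unknown")))
    if rec.duration < 30.0:
        raise ValueError(f"{path.name}: recording shorter than 30 s")
    return rec
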