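"""Plain-text readers/writers shared by all stages.

Recordings travel as a long-format CSV (subject_id, replicate,
channel_type, sensor_index, time_s, value) with a JSON sidecar holding
the generating settings; feature tables and metadata are CSV; analysis
reports are versioned JSON with SHA-256 digests of their inputs.  All
floats are written with full precision so round trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FEATURE_NAMES, N_SENSORS, SensorRecording

__all__ = [
    "SchemaError", "write_recordings", "read_recordings",
    "write_features", "read_features", "write_report", "sha256_file",
]

RECORDING_COLUMNS = ["subject_id", "replicate", "channel_type",
                     "sensor_index", "time_s", "value"]


class SchemaError(ValueError):
    """A file does not conform to the documented table schema."""


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_recordings(recordings: list[SensorRecording], csv_path,
                     sidecar: dict | None = None) -> None:
    """Write recordings as long-format CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    frames = []
    for rec in recordings:
        T = rec.n_samples
        for kind, block in (("exhaled", rec.exhaled), ("ambient", rec.ambient)):
            frames.append(pd.DataFrame({
                "subject_id": np.repeat(rec.subject_id, N_SENSORS * T),
                "replicate": rec.replicate,
                "channel_type": kind,
                "sensor_index": np.repeat(np.arange(1, N_SENSORS + 1), T),
                "time_s": np.tile(rec.time_s, N_SENSORS),
                "value": block.reshape(-1),
            }))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=RECORDING_COLUMNS))
    table.to_csv(csv_path, index=False)
    meta = dict(sidecar or {})
    if recordings:
        meta.setdefault("sample_rate_hz", recordings[0].sample_rate_hz)
    meta.setdefault("schema", RECORDING_COLUMNS)
    csv_path.with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))


def read_recordings(csv_path, sample_rate_hz: float | None = None
                    ) -> list[SensorRecording]:
    """Read a long-format recording CSV back into SensorRecording objects.

    Validation failures (bad sensor index, unknown channel type, unsorted
    time) raise :class:`SchemaError` naming the offending rows.  An empty
    file yields an empty list with a warning.
    """
    csv_path = Path(csv_path)
    try:
        table = pd.read_csv(csv_path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{csv_path} is empty; no recordings read")
        return []
    if table.empty:
        warnings.warn(f"{csv_path} has no rows; no recordings read")
        return []
    missing = [c for c in RECORDING_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    bad = ~table["sensor_index"].isin(range(1, N_SENSORS + 1))
    if bad.any():
        rows = (table.index[bad] + 2).tolist()[:5]  # 1-based incl. header
        raise SchemaError(f"sensor_index outside 1..{N_SENSORS} at rows {rows}")
    badk = ~table["channel_type"].isin(["exhaled", "ambient"])
    if badk.any():
        rows = (table.index[badk] + 2).tolist()[:5]
        raise SchemaError(f"invalid channel_type at rows {rows}")

    if sample_rate_hz is None:
        sidecar = csv_path.with_suffix(".json")
        if sidecar.exists():
            sample_rate_hz = json.loads(sidecar.read_text()).get("sample_rate_hz")

    recordings = []
    for (sid, rep), grp in table.groupby(["subject_id", "replicate"],
                                         sort=True):
        blocks = {}
        t_ref = None
        for (kind, sensor), chan in grp.groupby(["channel_type",
                                                 "sensor_index"], sort=True):
            t = chan["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                first = int(chan.index[0]) + 2
                raise SchemaError(
                    f"time_s not strictly increasing for subject {sid} "
                    f"replicate {rep} {kind} sensor {sensor} "
                    f"(block starting at row {first})")
            blocks.setdefault(kind, {})[int(sensor)] = chan["value"].to_numpy()
            t_ref = t
        for kind in ("exhaled", "ambient"):
            if set(blocks.get(kind, {})) != set(range(1, N_SENSORS + 1)):
                raise SchemaError(
                    f"subject {sid} replicate {rep} lacks the full "
                    f"7-sensor {kind} array")
        ex = np.vstack([blocks["exhaled"][s] for s in range(1, N_SENSORS + 1)])
        am = np.vstack([blocks["ambient"][s] for s in range(1, N_SENSORS + 1)])
        rate = sample_rate_hz
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(t_ref)))
        recordings.append(SensorRecording(
            subject_id=str(sid), replicate=int(rep), time_s=t_ref,
            exhaled=ex, ambient=am, sample_rate_hz=float(rate)))
    return recordings


def write_features(features: pd.DataFrame, path) -> None:
    cols = ["subject_id", *FEATURE_NAMES, "qc_ok", "qc_flags"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    features.loc[:, cols].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False,
                        na_values=["", "nan", "NaN"],
                        float_precision="round_trip")
    missing = [c for c in ("subject_id", *FEATURE_NAMES, "qc_ok")
               if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        dup = table["subject_id"][table["subject_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate subject_id {dup!r}")
    table["qc_ok"] = table["qc_ok"].astype(bool)
    return table


_REQUIRED_REPORT_FIELDS = ("schema_version", "analysis", "status", "config",
                           "results")


def write_report(report: dict, path, input_paths: dict | None = None) -> dict:
    """Serialise an analysis report to JSON with input digests.

    ``report`` is the dict from :meth:`AnalysisReport.to_dict`; missing
    required fields are refused by name.  Returns the manifest written
    (report + ``inputs`` digest map); identical inputs reproduce
    identical bytes.
    """
    missing = [f for f in _REQUIRED_REPORT_FIELDS if f not in report]
    if missing:
        raise SchemaError(f"report missing required fields: {missing}")
    manifest = dict(report)
    manifest["inputs"] = {
        name: {"path": str(p), "sha256": sha256_file(p)}
        for name, p in (input_paths or {}).items()}
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
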