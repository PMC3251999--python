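"""Readers/writers for the toolkit's on-disk formats.

Formats: 8-bit grayscale PNG/PGM images (intensities scaled to [0, 1],
masks binarized at 0.5 and written as 0/255), silhouette sequences as a
manifest text file listing frame files in order, sensor corpora and
segment tables as CSV, event/decision streams as JSON lines with
ISO-8601 timestamps, and a versioned JSON model archive whose float
payloads round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ArchiveError, ContractError, FormatError
from .rules import ActivityEvent, Decision
from .semicrf.segments import SemiSegment

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_sequence_manifest",
    "write_sequence_manifest",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_segments_csv",
    "write_segments_csv",
    "read_events_jsonl",
    "write_events_jsonl",
    "write_decisions_jsonl",
    "save_model",
    "load_model",
    "read_config",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/PGM as float intensities in [0, 1]."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: only 8-bit grayscale is supported, got {arr.dtype}")
    if arr.ndim == 3:
        if arr.shape[2] not in (1,) and not np.all(arr[..., :1] == arr[..., :3]):
            raise FormatError(f"{path}: color images are not supported")
        arr = arr[..., 0]
    return arr.astype(float) / 255.0


def write_image(image: np.ndarray, path) -> None:
    """Write [0, 1] intensities as 8-bit grayscale (PNG or PGM by suffix)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a mask image; pixels >= 0.5 are foreground."""
    return read_image(path) >= 0.5


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a 0/255 image (lossless round-trip)."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_sequence_manifest(frames, directory, stem: str = "frame") -> Path:
    """Write silhouette frames plus a manifest listing them in order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(frames):
        name = f"{stem}_{i:04d}.png"
        write_mask(frame, directory / name)
        names.append(name)
    manifest = directory / "manifest.txt"
    manifest.write_text("\n".join(names) + "\n")
    return manifest


def read_sequence_manifest(manifest) -> np.ndarray:
    """Read the frames named by a manifest file, preserving its order."""
    manifest = Path(manifest)
    if not manifest.is_file():
        raise FormatError(f"manifest {manifest} does not exist")
    names = [line.strip() for line in manifest.read_text().splitlines() if line.strip()]
    if not names:
        raise FormatError(f"manifest {manifest} lists no frames")
    frames = [read_mask(manifest.parent / name) for name in names]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"manifest {manifest}: frames have differing shapes")
    return np.stack(frames)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_sensor_csv(corpus, path) -> None:
    """Write ``[(symbols, labels), ...]`` as CSV with columns
    seq, time, symbol, label (time is the 1-based step)."""
    rows = []
    for i, (symbols, labels) in enumerate(corpus):
        for t, (s, lab) in enumerate(zip(symbols, labels), start=1):
            rows.append((i, t, int(s), int(lab)))
    pd.DataFrame(rows, columns=["seq", "time", "symbol", "label"]).to_csv(
        path, index=False
    )


def read_sensor_csv(path):
    """Inverse of :func:`write_sensor_csv`; validates time monotonicity."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read sensor CSV {path}: {exc}") from exc
    required = {"seq", "time", "symbol", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    corpus = []
    for seq_id, grp in df.groupby("seq", sort=True):
        times = grp["time"].to_numpy()
        if np.any(np.diff(times) <= 0):
            row = int(grp.index[np.argmax(np.diff(times) <= 0) + 1]) + 2
            raise FormatError(f"{path}: non-monotone time at row {row}")
        corpus.append((grp["symbol"].to_numpy(int), grp["label"].to_numpy(int)))
    return corpus


def write_segments_csv(segments, path) -> None:
    """Write segments as CSV (label, begin, end), 1-based inclusive."""
    pd.DataFrame(
        [(s.y, s.b, s.e) for s in segments], columns=["label", "begin", "end"]
    ).to_csv(path, index=False)


def read_segments_csv(path):
    """Inverse of :func:`write_segments_csv`; cites the offending row on error."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read segments CSV {path}: {exc}") from exc
    missing = {"label", "begin", "end"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        b, e = int(row["begin"]), int(row["end"])
        if e < b or b < 1:
            raise FormatError(f"{path}: invalid segment at row {i + 2} (begin={b}, end={e})")
        out.append(SemiSegment(row["label"], b, e))
    return out


# ---------------------------------------------------------------------------
# Events / decisions (JSON lines)
# ---------------------------------------------------------------------------

_EVENT_FIELDS = ("id", "name", "type", "time", "person")


def write_events_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            rec = asdict(ev)
            rec["time"] = ev.time.isoformat()
            fh.write(json.dumps(rec) + "\n")


def read_events_jsonl(path):
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: bad JSON on line {lineno}") from exc
            missing = [f for f in _EVENT_FIELDS if not rec.get(f)]
            if missing:
                raise FormatError(
                    f"{path}: line {lineno} missing fields {missing}"
                )
            events.append(ActivityEvent(
                id=str(rec["id"]), name=str(rec["name"]), type=str(rec["type"]),
                time=datetime.fromisoformat(rec["time"]), person=str(rec["person"]),
                location=str(rec.get("location", "")),
                consequent_action=rec.get("consequent_action"),
            ))
    return events


def write_decisions_jsonl(decisions, path) -> None:
    with open(path, "w") as fh:
        for d in decisions:
            rec = {"kind": d.kind, "payload": d.payload,
                   "triggers": list(d.triggers), "time": d.time.isoformat()}
            fh.write(json.dumps(rec) + "\n")


def read_decisions_jsonl(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(Decision(
                kind=rec["kind"], payload=rec["payload"],
                triggers=tuple(rec["triggers"]),
                time=datetime.fromisoformat(rec["time"]),
            ))
    return out


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"])
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_model(payload: dict, path, kind: str = "model") -> None:
    """Write a versioned model archive (JSON; floats round-trip exactly)."""
    doc = {"schema_version": SCHEMA_VERSION, "kind": kind, "payload": _encode(payload)}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path, kind: str | None = None, required: tuple = ()) -> dict:
    """Read a model archive; rejects version mismatches and names any
    missing required payload field."""
    try:
        doc = json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise ArchiveError(f"cannot read archive {path}: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ArchiveError(
            f"{path}: schema version {doc.get('schema_version')!r} is not "
            f"supported (expected {SCHEMA_VERSION})"
        )
    if kind is not None and doc.get("kind") != kind:
        raise ArchiveError(f"{path}: archive kind {doc.get('kind')!r}, expected {kind!r}")
    payload = _decode(doc.get("payload", {}))
    for field in required:
        if field not in payload:
            raise ArchiveError(f"{path}: archive is missing required field {field!r}")
    return payload


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Plain key=value config; values parsed as int/float when possible."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}: line {lineno} is not key=value")
        key, _, value = line.partition("=")
        value = value.strip()
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        out[key.strip()] = value
    return out
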