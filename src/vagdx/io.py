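"""Text-format persistence: recordings, feature tables, evaluation reports.

Recordings are stored one per CSV file: ``#``-prefixed metadata header lines
(acquisition constants, subject fields, the raw 10 Hz encoder series, and
any generator ground truth as JSON), then a column header, then rows of
(time_s, acoustic count, encoder degrees) with the encoder zero-order-held
to the acoustic clock so the two channels share one time base.

Dialect is fixed: comma delimiter, ``.`` decimal, LF line endings, UTF-8.
All writers are idempotent (no timestamps in the payload) and round-trip
exactly: integer samples bit-for-bit, floats via repr.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Chain, Group, RawRecording, Sex, SubjectProfile

_REQUIRED_KEYS = (
    "subject_id", "group", "icrs_grade", "age", "sex", "height", "weight",
    "bmi", "chain", "fs_acoustic", "fs_encoder", "quant_bits", "encoder_raw",
)

FEATURE_COLUMNS = ["mv", "sa", "rms", "pv", "ppv", "cf", "if_", "sf",
                   "var", "kur", "m6a", "m8a"]
CASE_COLUMNS = ["case_id"] + FEATURE_COLUMNS + ["age", "sex", "bmi", "chain", "label"]


class RecordingFormatError(ValueError):
    pass


def write_recording(rec: RawRecording, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    s = rec.subject
    header = {
        "subject_id": s.subject_id,
        "group": s.group.value,
        "icrs_grade": s.icrs_grade,
        "age": repr(s.age),
        "sex": s.sex.value,
        "height": repr(s.height),
        "weight": repr(s.weight),
        "bmi": repr(s.bmi),
        "chain": rec.chain.value,
        "knee": rec.knee,
        "fs_acoustic": repr(rec.fs_acoustic),
        "fs_encoder": repr(rec.fs_encoder),
        "quant_bits": rec.quant_bits,
        "encoder_raw": ",".join(repr(float(v)) for v in rec.encoder),
        "truth": json.dumps(rec.truth, sort_keys=True),
    }
    n = rec.acoustic.size
    step = rec.fs_acoustic / rec.fs_encoder
    enc_idx = np.minimum((np.arange(n) / step).astype(int), rec.encoder.size - 1)
    held = rec.encoder[enc_idx] if rec.encoder.size else np.zeros(n)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# vagdx-recording v1\n")
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write("time_s,acoustic,encoder_deg\n")
        for i in range(n):
            fh.write(f"{i / rec.fs_acoustic!r},{int(rec.acoustic[i])},{held[i]!r}\n")


def read_recording(path: str | os.PathLike) -> RawRecording:
    path = os.fspath(path)
    meta: dict[str, str] = {}
    counts: list[int] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            payload = line[1:].strip()
            if "=" in payload:
                k, v = payload.split("=", 1)
                meta[k.strip()] = v
        else:
            body_start = i
            break
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise RecordingFormatError(
            f"{path}: missing required metadata keys: {', '.join(missing)}")
    if body_start is None or lines[body_start] != "time_s,acoustic,encoder_deg":
        raise RecordingFormatError(f"{path}: missing column header row")
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise RecordingFormatError(f"{path}:{lineno}: malformed row: {line!r}")
        try:
            counts.append(int(parts[1]))
        except ValueError as exc:
            raise RecordingFormatError(f"{path}:{lineno}: bad sample: {line!r}") from exc

    subject = SubjectProfile(
        subject_id=meta["subject_id"],
        group=Group(meta["group"]),
        icrs_grade=int(meta["icrs_grade"]),
        age=float(meta["age"]),
        sex=Sex(meta["sex"]),
        height=float(meta["height"]),
        weight=float(meta["weight"]),
        bmi=float(meta["bmi"]),
    )
    encoder = (np.array([float(v) for v in meta["encoder_raw"].split(",")])
               if meta["encoder_raw"] else np.empty(0))
    return RawRecording(
        subject=subject, chain=Chain(meta["chain"]),
        acoustic=np.array(counts, dtype=np.int32), encoder=encoder,
        fs_acoustic=float(meta["fs_acoustic"]), fs_encoder=float(meta["fs_encoder"]),
        quant_bits=int(meta["quant_bits"]), knee=meta.get("knee", ""),
        truth=json.loads(meta.get("truth", "{}")),
    )


def write_feature_table(rows: Sequence, path: str | os.PathLike) -> None:
    """One row per case, fixed column order; stable to 12 significant digits."""
    records = []
    for case in rows:
        d = {"case_id": case.case_id}
        d.update({k: getattr(case.features, k) for k in FEATURE_COLUMNS})
        d.update({"age": case.age, "sex": case.sex, "bmi": case.bmi,
                  "chain": case.chain.value, "label": case.label.value})
        records.append(d)
    df = pd.DataFrame(records, columns=CASE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report, path: str | os.PathLike) -> None:
    """Structured JSON text containing every report field (dataclass or dict)."""
    obj = dataclasses.asdict(report) if dataclasses.is_dataclass(report) else dict(report)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_report(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
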