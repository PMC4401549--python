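"""Event-table container and on-disk round-trip.

One :class:`EventTable` holds a single well's cells-by-channels intensity
matrix plus the well metadata (patient, tissue, modulator, exposure time,
plate).  Two dialects are supported on disk:

* **CSV** — header ``event_index,FSC,SSC,AquaAmine,...``, UTF-8, '.'
  decimal, with a JSON sidecar ``<path>.json`` carrying the well metadata.
  Lossless for float64 values (written with repr precision).
* **FCS3** — a minimal FCS 3.1 single-dataset file, list-mode float32
  little-endian, metadata stored as custom TEXT keywords.  Round-trips
  channel values at float32 precision.  The writer/reader here covers only
  this profile, not the full FCS zoo (no integer data, no multi-dataset
  files, no analysis segments).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EventTable", "write_events", "read_events", "EventFileError"]


class EventFileError(ValueError):
    """Malformed event file; message names the offending offset or line."""


@dataclass
class EventTable:
    """One well's single-cell intensity matrix plus well metadata."""

    well_id: str
    patient_id: str
    tissue: str
    modulator: str
    time_hours: float
    data: pd.DataFrame
    plate_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("channel names must be unique")

    @property
    def n_events(self) -> int:
        return int(len(self.data))

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def replace(self, **kw) -> "EventTable":
        return _dc_replace(self, **kw)

    def _meta_dict(self) -> dict:
        return {"well_id": self.well_id, "patient_id": self.patient_id,
                "tissue": self.tissue, "modulator": self.modulator,
                "time_hours": self.time_hours, "plate_id": self.plate_id,
                "meta": self.meta}


def write_events(table: EventTable, path, dialect: str = "csv") -> Path:
    path = Path(path)
    if dialect == "csv":
        _write_csv(table, path)
    elif dialect == "fcs3":
        _write_fcs(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_events(path, dialect: str = "csv") -> EventTable:
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "fcs3":
        return _read_fcs(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(table: EventTable, path: Path) -> None:
    df = table.data.copy()
    df.insert(0, "event_index", np.arange(table.n_events))
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(table._meta_dict(), indent=1),
                       encoding="utf-8")


def _read_csv(path: Path) -> EventTable:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise EventFileError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # pandas reports the offending line itself
        raise EventFileError(f"{path}: {exc}") from exc
    if len(df.columns) == 0 or df.columns[0] != "event_index":
        raise EventFileError(f"{path}: line 1: header must start with 'event_index'")
    df = df.drop(columns=["event_index"])
    return EventTable(data=df, **{k: meta[k] for k in
                                  ("well_id", "patient_id", "tissue",
                                   "modulator", "time_hours", "plate_id",
                                   "meta")})


# ---------------------------------------------------------------------------
# Minimal FCS 3.1 (list mode, float32, little-endian, single dataset)
# ---------------------------------------------------------------------------

_DELIM = "/"
_META_KEYS = ("well_id", "patient_id", "tissue", "modulator", "time_hours",
              "plate_id")


def _write_fcs(table: EventTable, path: Path) -> None:
    values = table.data.to_numpy(dtype=np.float32)
    n_events, n_par = values.shape if values.size else (0, len(table.channels))
    n_par = len(table.channels)
    data_bytes = values.astype("<f4").tobytes()

    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0", "$NEXTDATA": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$TOT": str(n_events), "$PAR": str(n_par),
    }
    for i, ch in enumerate(table.channels, start=1):
        kw[f"$P{i}N"] = ch
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    for key in _META_KEYS:
        kw[f"#SCNP_{key.upper()}"] = str(getattr(table, key))
    kw["#SCNP_META"] = json.dumps(table.meta)

    # two-pass offset computation: write data offsets with fixed 10-digit
    # fields so TEXT length is independent of their values
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10

    def render(d):
        parts = [_DELIM]
        for k, v in d.items():
            if _DELIM in k or (_DELIM in v):
                raise EventFileError(f"delimiter character in keyword {k!r}")
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render(kw)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1 if data_bytes else 0
    kw["$BEGINDATA"] = f"{data_begin:010d}"
    kw["$ENDDATA"] = f"{max(data_end, 0):010d}"
    text = render(kw)

    def hfield(x):
        s = str(x)
        if len(s) > 8:
            s = "0"  # out-of-range offsets go to TEXT per the standard
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + hfield(text_begin) + hfield(text_end)
    header += hfield(data_begin if data_bytes else 0)
    header += hfield(data_end if data_bytes else 0)
    header += hfield(0) + hfield(0)
    assert len(header) == header_len
    path.write_bytes(header + text + data_bytes)


def _read_fcs(path: Path) -> EventTable:
    raw = path.read_bytes()
    if len(raw) < 58 or not raw.startswith(b"FCS3"):
        raise EventFileError(f"{path}: offset 0: not an FCS 3.x file")

    def hfield(i):
        s = raw[10 + 8 * i: 18 + 8 * i].decode("ascii", "replace").strip()
        try:
            return int(s) if s else 0
        except ValueError:
            raise EventFileError(
                f"{path}: offset {10 + 8 * i}: bad header field {s!r}")

    text_begin, text_end = hfield(0), hfield(1)
    if not (0 < text_begin <= text_end < len(raw)):
        raise EventFileError(f"{path}: offset 10: TEXT segment out of range")
    text = raw[text_begin:text_end + 1].decode("ascii", "replace")
    delim = text[0]
    parts = text[1:].split(delim)
    if len(parts) < 2:
        raise EventFileError(f"{path}: offset {text_begin}: empty TEXT segment")
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    for req in ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD"):
        if req not in kw:
            raise EventFileError(f"{path}: TEXT segment missing {req}")
    if kw["$DATATYPE"] != "F" or kw["$BYTEORD"] != "1,2,3,4":
        raise EventFileError(
            f"{path}: only float32 little-endian data supported "
            f"(got $DATATYPE={kw['$DATATYPE']}, $BYTEORD={kw['$BYTEORD']})")
    n_events, n_par = int(kw["$TOT"]), int(kw["$PAR"])
    channels = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    if n_events > 0:
        data_begin = int(kw.get("$BEGINDATA") or hfield(2))
        data_end = int(kw.get("$ENDDATA") or hfield(3))
        expected = n_events * n_par * 4
        blob = raw[data_begin:data_end + 1]
        if len(blob) != expected:
            raise EventFileError(
                f"{path}: offset {data_begin}: DATA segment has {len(blob)} "
                f"bytes, expected {expected}")
        values = np.frombuffer(blob, dtype="<f4").reshape(n_events, n_par)
    else:
        values = np.empty((0, n_par), dtype=np.float32)
    df = pd.DataFrame(values, columns=channels)

    meta = json.loads(kw.get("#SCNP_META", "{}"))
    fields = {k: kw.get(f"#SCNP_{k.upper()}", "") for k in _META_KEYS}
    fields["time_hours"] = float(fields["time_hours"] or 0.0)
    return EventTable(data=df, meta=meta, **fields)
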