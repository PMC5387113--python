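"""Patient identification and reading storage behind pluggable back-ends.

Storage is the framework's main extension point ("hot spot"): the
monitoring pipeline only sees the :class:`ReadingStore` contract —
append, query by patient/sensor/time-range, read-your-writes, timestamp
ordering — and any conforming back-end plugs in via
:func:`register_backend`.  Two back-ends ship: in-memory and local
JSON-lines.  A remote/REST back-end is an extension point only.

A :class:`BufferedStore` wrapper implements the cached-storage strategy:
appends against an unavailable back-end are buffered locally and flushed
once the back-end recovers, so transient outages lose no data.

Time ranges are half-open ``[t_from, t_to)``.  Readings are immutable once
appended; an identical re-append is a no-op (idempotence).
"""

from __future__ import annotations

import csv
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .core import (
    Activity,
    Instant,
    Modality,
    PatientProfile,
    Reading,
    Sex,
    SignalQuality,
    format_timestamp,
    parse_timestamp,
)
from .errors import IntegrityError, OrderingError, StoreUnavailableError

__all__ = [
    "ReadingStore",
    "InMemoryStore",
    "JsonLinesStore",
    "BufferedStore",
    "register_backend",
    "create_store",
    "available_backends",
    "PatientRegistry",
    "resolve_identity",
    "reading_to_dict",
    "reading_from_dict",
    "write_readings_csv",
    "read_readings_csv",
]

READING_CSV_COLUMNS = [
    "patient_id",
    "sensor_id",
    "modality",
    "timestamp",
    "value",
    "signal_quality",
    "activity",
]


def reading_to_dict(reading: Reading) -> dict:
    return {
        "patient_id": reading.patient_id,
        "sensor_id": reading.sensor_id,
        "modality": reading.modality.value,
        "timestamp": format_timestamp(reading.timestamp),
        "value": reading.value,
        "signal_quality": reading.signal_quality.value,
        "activity": reading.activity.value,
    }


def reading_from_dict(data: dict) -> Reading:
    return Reading(
        patient_id=data["patient_id"],
        sensor_id=data["sensor_id"],
        modality=Modality(data["modality"]),
        timestamp=parse_timestamp(data["timestamp"]),
        value=float(data["value"]),
        signal_quality=SignalQuality(data.get("signal_quality", "good")),
        activity=Activity(data.get("activity", "unknown")),
    )


def _dedup_key(reading: Reading) -> tuple:
    return (reading.patient_id, reading.sensor_id, reading.timestamp.dt, reading.value)


class ReadingStore(ABC):
    """Contract every storage back-end must honour.

    * append-then-query returns the appended reading (read-your-writes);
    * query results are ordered by timestamp (ties in append order);
    * duplicate appends of an identical (patient, sensor, timestamp,
      value) tuple store one copy.
    """

    name: str = "abstract"

    @abstractmethod
    def append(self, reading: Reading) -> dict:
        """Durably store a reading; returns a receipt dict."""

    @abstractmethod
    def query(
        self,
        patient_id: str | None = None,
        sensor_id: str | None = None,
        t_from: Instant | None = None,
        t_to: Instant | None = None,
    ) -> list[Reading]:
        """Readings in the half-open window [t_from, t_to), timestamp-ordered."""

    def high_water_mark(self, patient_id: str, sensor_id: str) -> Instant | None:
        """Latest stored timestamp for one stream, or None if empty."""
        readings = self.query(patient_id=patient_id, sensor_id=sensor_id)
        return readings[-1].timestamp if readings else None


def _check_range(t_from: Instant | None, t_to: Instant | None) -> None:
    if t_from is not None and t_to is not None and t_to < t_from:
        raise OrderingError(
            f"inverted query range: {format_timestamp(t_from)} > {format_timestamp(t_to)}"
        )


def _select(
    readings: Iterable[Reading],
    patient_id: str | None,
    sensor_id: str | None,
    t_from: Instant | None,
    t_to: Instant | None,
) -> Iterator[Reading]:
    for r in readings:
        if patient_id is not None and r.patient_id != patient_id:
            continue
        if sensor_id is not None and r.sensor_id != sensor_id:
            continue
        if t_from is not None and r.timestamp < t_from:
            continue
        if t_to is not None and not r.timestamp < t_to:
            continue
        yield r


class InMemoryStore(ReadingStore):
    """Reference back-end: a list plus a dedup set."""

    name = "memory"

    def __init__(self) -> None:
        self._readings: list[Reading] = []
        self._seen: set[tuple] = set()

    def append(self, reading: Reading) -> dict:
        key = _dedup_key(reading)
        if key in self._seen:
            return {"status": "duplicate"}
        self._seen.add(key)
        self._readings.append(reading)
        return {"status": "stored"}

    def query(self, patient_id=None, sensor_id=None, t_from=None, t_to=None) -> list[Reading]:
        _check_range(t_from, t_to)
        out = list(_select(self._readings, patient_id, sensor_id, t_from, t_to))
        out.sort(key=lambda r: r.timestamp.dt)  # stable: ties keep append order
        return out


class JsonLinesStore(ReadingStore):
    """Local durable back-end: one JSON object per line, append-only."""

    name = "jsonl"

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self._seen: set[tuple] = set()
        if self.path.exists():
            for r in self._iter_file():
                self._seen.add(_dedup_key(r))

    def _iter_file(self) -> Iterator[Reading]:
        if not self.path.exists():
            return
        with self.path.open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield reading_from_dict(json.loads(line))

    def append(self, reading: Reading) -> dict:
        key = _dedup_key(reading)
        if key in self._seen:
            return {"status": "duplicate"}
        with self.path.open("a") as fh:
            fh.write(json.dumps(reading_to_dict(reading), sort_keys=True) + "\n")
        self._seen.add(key)
        return {"status": "stored"}

    def query(self, patient_id=None, sensor_id=None, t_from=None, t_to=None) -> list[Reading]:
        _check_range(t_from, t_to)
        out = list(_select(self._iter_file(), patient_id, sensor_id, t_from, t_to))
        out.sort(key=lambda r: r.timestamp.dt)
        return out


class BufferedStore(ReadingStore):
    """Cached-storage wrapper: buffer appends while the back-end is down.

    ``available`` is a probe callable (or plain flag via
    :meth:`set_available`); while it reports False, appends land in a local
    buffer and queries raise :class:`StoreUnavailableError`.  When the
    back-end recovers, the buffer is flushed in append order before the
    next operation proceeds.
    """

    name = "buffered"

    def __init__(self, inner: ReadingStore, available: Callable[[], bool] | None = None):
        self.inner = inner
        self._available = available if available is not None else (lambda: self._flag)
        self._flag = True
        self.buffer: list[Reading] = []

    def set_available(self, up: bool) -> None:
        self._flag = up

    def _flush(self) -> None:
        while self.buffer:
            self.inner.append(self.buffer.pop(0))

    def append(self, reading: Reading) -> dict:
        if not self._available():
            self.buffer.append(reading)
            return {"status": "buffered", "pending": len(self.buffer)}
        self._flush()
        return self.inner.append(reading)

    def query(self, patient_id=None, sensor_id=None, t_from=None, t_to=None) -> list[Reading]:
        if not self._available():
            raise StoreUnavailableError(f"back-end {self.inner.name!r} unavailable")
        self._flush()
        return self.inner.query(patient_id, sensor_id, t_from, t_to)


# -- plugin registry ---------------------------------------------------------

_BACKENDS: dict[str, Callable[..., ReadingStore]] = {}


def register_backend(name: str, factory: Callable[..., ReadingStore]) -> None:
    """Register a storage back-end under a name (the hot-spot mechanism)."""
    if name in _BACKENDS:
        raise IntegrityError(f"storage back-end {name!r} already registered")
    _BACKENDS[name] = factory


def create_store(name: str, **kwargs) -> ReadingStore:
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise IntegrityError(
            f"unknown storage back-end {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return factory(**kwargs)


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


register_backend("memory", InMemoryStore)
register_backend("jsonl", JsonLinesStore)


# -- identification ----------------------------------------------------------


@dataclass
class PatientRegistry:
    """Patients keyed by id and by RFID tag; both must be unique."""

    patients: dict[str, PatientProfile] = field(default_factory=dict)
    _by_tag: dict[str, PatientProfile] = field(default_factory=dict)
    quarantine: list[tuple[str, Reading]] = field(default_factory=list)

    def add(self, profile: PatientProfile) -> None:
        if profile.patient_id in self.patients:
            raise IntegrityError(f"duplicate patient_id {profile.patient_id!r}")
        tag = profile.rfid_tag.lower()
        if tag in self._by_tag:
            raise IntegrityError(f"duplicate rfid_tag {profile.rfid_tag!r}")
        self.patients[profile.patient_id] = profile
        self._by_tag[tag] = profile

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "PatientRegistry":
        reg = cls()
        for rec in records:
            reg.add(
                PatientProfile(
                    patient_id=rec["patient_id"],
                    rfid_tag=rec["rfid_tag"],
                    name=rec.get("name", ""),
                    age=int(rec.get("age", 0)),
                    sex=Sex(rec.get("sex", "other")),
                    location=rec.get("location", ""),
                )
            )
        return reg

    @classmethod
    def load(cls, path: str | Path) -> "PatientRegistry":
        """Load a registry from CSV or JSON (list of patient records)."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_records(json.loads(path.read_text()))
        with path.open(newline="") as fh:
            return cls.from_records(csv.DictReader(fh))


def resolve_identity(tag: str, registry: PatientRegistry) -> PatientProfile | None:
    """Look up the patient wearing an RFID tag; None if unknown.

    Readings arriving under an unknown tag should be quarantined by the
    caller (``registry.quarantine``), never dropped.
    """
    return registry._by_tag.get(tag.lower())


# -- CSV import/export -------------------------------------------------------


def write_readings_csv(readings: Iterable[Reading], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=READING_CSV_COLUMNS)
        writer.writeheader()
        for r in readings:
            writer.writerow(reading_to_dict(r))
    return path


def read_readings_csv(path: str | Path) -> list[Reading]:
    with Path(path).open(newline="") as fh:
        return [reading_from_dict(row) for row in csv.DictReader(fh)]
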