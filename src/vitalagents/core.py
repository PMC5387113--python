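"""Domain types for rule-based remote patient monitoring.

The package models a telemonitoring workflow in which autonomous software
agents watch streams of vital-sign readings, flag values outside a
patient-specific *desired value range* (DVR), and notify the responsible
health providers.  Five timestamps bracket the workflow:

* **T1** — the monitoring agent retrieves patient data and analyses it;
* **T2** — an anomaly is detected;
* **T3** — the notification routine starts;
* **T4** — the notification message is sent;
* **T5** — the provider receives the message (known only at minute
  resolution, emulating SMS receipt).

Four intervals summarise responsiveness: DAI = T2−T1, NSI = T3−T2,
NP = T4−T3 and NRI = T5−T4.

All timestamps live on a simulated clock at one-second resolution so the
whole pipeline is a deterministic function of its configuration.  The
telemetry text dialect is ``YYYY-MM-DD-HHMMSS`` (second resolution) or
``YYYY-MM-DD-HHMM`` (minute resolution, used for T5); ISO-8601 is accepted
on input as a convenience alias.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
import re
from dataclasses import dataclass, field

from .errors import OrderingError, TimestampFormatError

__all__ = [
    "Modality",
    "MODALITY_UNITS",
    "SignalQuality",
    "Activity",
    "Sex",
    "Channel",
    "Side",
    "Instant",
    "parse_timestamp",
    "format_timestamp",
    "interval_seconds",
    "PatientProfile",
    "SensorSpec",
    "Reading",
    "DesiredValueRange",
    "AnomalyRule",
    "AnomalyEvent",
    "NotificationRoute",
    "NotificationRecord",
    "DelayRow",
    "DelayReport",
    "DEFAULT_EPOCH",
]


class Modality(str, enum.Enum):
    """Sensor modality; the unit is fixed per modality."""

    HEART_RATE = "heart_rate"
    BODY_TEMPERATURE = "body_temperature"
    SPO2 = "spo2"
    ACCELEROMETER = "accelerometer"
    SIGNAL_QUALITY_CHANNEL = "signal_quality_channel"


MODALITY_UNITS: dict[Modality, str] = {
    Modality.HEART_RATE: "bpm",
    Modality.BODY_TEMPERATURE: "degC",
    Modality.SPO2: "%",
    Modality.ACCELEROMETER: "g",
    Modality.SIGNAL_QUALITY_CHANNEL: "dimensionless",
}


class SignalQuality(str, enum.Enum):
    GOOD = "good"
    POOR = "poor"
    MISSING = "missing"


class Activity(str, enum.Enum):
    REST = "rest"
    ACTIVE = "active"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"


class Channel(str, enum.Enum):
    SMS = "sms"
    EMAIL = "email"
    VOICE = "voice"
    BLUETOOTH = "bluetooth"
    CONSOLE = "console"


class Side(str, enum.Enum):
    """Which side of the DVR an anomaly rule covers."""

    BELOW_LOW = "below_low"
    ABOVE_HIGH = "above_high"


# ---------------------------------------------------------------------------
# Instants and the telemetry timestamp dialect
# ---------------------------------------------------------------------------

#: Default epoch mapping simulated second 0 onto a calendar instant.
DEFAULT_EPOCH = _dt.datetime(2016, 11, 4, 17, 34, 0)

_FINE_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})-(\d{2})(\d{2})(\d{2})$")
_COARSE_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})-(\d{2})(\d{2})$")


@dataclass(frozen=True, order=True)
class Instant:
    """A simulated-clock instant at one-second resolution.

    ``coarse`` marks minute-resolution instants (T5 as printed in telemetry
    exports); it does not participate in ordering or equality, so a coarse
    17:34 equals a fine 17:34:00.
    """

    dt: _dt.datetime
    coarse: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.dt.microsecond:
            raise TimestampFormatError("sub-second resolution is not supported")
        if self.coarse and self.dt.second:
            raise TimestampFormatError("coarse instants must fall on a whole minute")

    def plus(self, seconds: int) -> "Instant":
        return Instant(self.dt + _dt.timedelta(seconds=int(seconds)), coarse=self.coarse)

    def floor_minute(self) -> "Instant":
        return Instant(self.dt.replace(second=0), coarse=True)


def _check_fields(parts: dict[str, int]) -> None:
    bounds = {
        "month": (1, 12),
        "day": (1, 31),
        "hour": (0, 23),
        "minute": (0, 59),
        "second": (0, 59),
    }
    for name, (lo, hi) in bounds.items():
        if name in parts and not lo <= parts[name] <= hi:
            raise TimestampFormatError(
                f"{name} out of range: {parts[name]} (expected {lo}-{hi})"
            )


def parse_timestamp(text: str) -> Instant:
    """Parse a telemetry timestamp.

    Accepts ``YYYY-MM-DD-HHMMSS`` (second resolution) or ``YYYY-MM-DD-HHMM``
    (minute resolution, flagged coarse).  ISO-8601 at second resolution is
    accepted as an input alias; output always uses the telemetry dialect.
    """
    if not isinstance(text, str):
        raise TimestampFormatError(f"expected a string, got {type(text).__name__}")
    text = text.strip()
    m = _FINE_RE.match(text)
    coarse = False
    if m is None:
        m = _COARSE_RE.match(text)
        coarse = m is not None
    if m is not None:
        names = ["year", "month", "day", "hour", "minute"] + ([] if coarse else ["second"])
        parts = {n: int(v) for n, v in zip(names, m.groups())}
        _check_fields(parts)
        try:
            dt = _dt.datetime(**parts)
        except ValueError as exc:  # e.g. Feb 30
            raise TimestampFormatError(f"invalid calendar date in {text!r}: {exc}") from exc
        return Instant(dt, coarse=coarse)
    # ISO-8601 alias
    try:
        dt = _dt.datetime.fromisoformat(text)
    except ValueError:
        raise TimestampFormatError(
            f"timestamp {text!r} matches neither YYYY-MM-DD-HHMMSS, "
            "YYYY-MM-DD-HHMM nor ISO-8601"
        ) from None
    if dt.tzinfo is not None:
        raise TimestampFormatError("time zones are not supported")
    if dt.microsecond:
        raise TimestampFormatError("sub-second resolution is not supported")
    return Instant(dt)


def format_timestamp(instant: Instant) -> str:
    """Render an instant in the telemetry dialect (coarse → minute form)."""
    if instant.coarse:
        return instant.dt.strftime("%Y-%m-%d-%H%M")
    return instant.dt.strftime("%Y-%m-%d-%H%M%S")


def interval_seconds(a: Instant, b: Instant) -> int:
    """Exact non-negative interval b − a in whole seconds.

    Both instants must be at second resolution; ``b < a`` raises
    :class:`OrderingError` (it signals corrupted telemetry).
    """
    if a.coarse or b.coarse:
        raise TimestampFormatError("interval_seconds requires second-resolution instants")
    delta = (b.dt - a.dt).total_seconds()
    if delta < 0:
        raise OrderingError(
            f"interval end {format_timestamp(b)} precedes start {format_timestamp(a)}"
        )
    return int(delta)


# ---------------------------------------------------------------------------
# Patients, sensors, readings
# ---------------------------------------------------------------------------

_HEX_RE = re.compile(r"^[0-9a-fA-F]+$")


@dataclass(frozen=True)
class PatientProfile:
    """A monitored patient, identified by an opaque id and an RFID tag."""

    patient_id: str
    rfid_tag: str
    name: str
    age: int
    sex: Sex
    location: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not _HEX_RE.match(self.rfid_tag):
            raise ValueError(f"rfid_tag must be a hex string, got {self.rfid_tag!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")


@dataclass(frozen=True)
class SensorSpec:
    """One physical sensor: modality, unit and sampling period."""

    sensor_id: str
    modality: Modality
    unit: str
    sample_period: int

    def __post_init__(self) -> None:
        expected = MODALITY_UNITS[self.modality]
        if self.unit != expected:
            raise ValueError(
                f"unit for {self.modality.value} must be {expected!r}, got {self.unit!r}"
            )
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")


@dataclass(frozen=True)
class Reading:
    """One timestamped measurement with signal-quality and activity context."""

    patient_id: str
    sensor_id: str
    modality: Modality
    timestamp: Instant
    value: float
    signal_quality: SignalQuality = SignalQuality.GOOD
    activity: Activity = Activity.UNKNOWN

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"reading value must be finite, got {self.value!r}")


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesiredValueRange:
    """The interval of values considered normal (bounds inclusive).

    A value ``v`` is normal iff ``low <= v <= high``; anomalies are the
    strict complement.  A range written 36.0–36.6 therefore treats exactly
    36.6 as normal and anything above it as anomalous.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("DVR bounds must be finite")
        if self.low > self.high:
            raise ValueError(f"DVR low {self.low} exceeds high {self.high}")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class AnomalyRule:
    """One side of the DVR complement, carrying a clinical label.

    Examples: values below a 36.0 °C bound → ``Hypothermia``; heart rates
    above 110 bpm → ``Tachyarrhythmias``.
    """

    side: Side
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("anomaly label must be non-empty")

    def matches(self, value: float, dvr: DesiredValueRange) -> bool:
        if self.side is Side.BELOW_LOW:
            return value < dvr.low
        return value > dvr.high


# ---------------------------------------------------------------------------
# Events, routes, records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnomalyEvent:
    """A reading judged anomalous: label plus retrieval (T1) and detection (T2)."""

    reading: Reading
    label: str
    t1: Instant
    t2: Instant

    def __post_init__(self) -> None:
        if self.t2 < self.t1:
            raise OrderingError(
                f"detection time T2 {format_timestamp(self.t2)} precedes "
                f"retrieval time T1 {format_timestamp(self.t1)}"
            )


@dataclass(frozen=True)
class NotificationRoute:
    """Routing of one anomaly label to one provider over one channel."""

    label: str
    provider_id: str
    channel: Channel
    address: str


@dataclass(frozen=True)
class NotificationRecord:
    """Outcome of dispatching one anomaly over one route.

    T5 is stored at minute resolution, emulating SMS receipts whose
    timestamps phones report without second precision; it may be absent for
    channels with no receipt signal.
    """

    event: AnomalyEvent
    route: NotificationRoute
    t3: Instant
    t4: Instant
    t5: Instant | None = None

    def __post_init__(self) -> None:
        if self.t3 < self.event.t2 or self.t4 < self.t3:
            raise OrderingError("notification timestamps must satisfy T2 <= T3 <= T4")
        if self.t5 is not None and self.t5.dt < self.t4.floor_minute().dt:
            raise OrderingError("receipt T5 precedes send T4")


@dataclass(frozen=True)
class DelayRow:
    """Per-notification delays in seconds.

    NRI is a (lower, upper) bound pair because T5 is only known to the
    minute: the true receipt lies somewhere in that minute.
    """

    record: NotificationRecord
    dai: int
    nsi: int
    np: int
    nri_lower: int | None = None
    nri_upper: int | None = None


@dataclass(frozen=True)
class DelayReport:
    """Delay rows plus arithmetic-mean aggregates (DAI, NSI, NP)."""

    rows: tuple[DelayRow, ...]

    @property
    def mean_dai(self) -> float:
        return sum(r.dai for r in self.rows) / len(self.rows) if self.rows else float("nan")

    @property
    def mean_nsi(self) -> float:
        return sum(r.nsi for r in self.rows) / len(self.rows) if self.rows else float("nan")

    @property
    def mean_np(self) -> float:
        return sum(r.np for r in self.rows) / len(self.rows) if self.rows else float("nan")

    def summary(self) -> dict[str, float | int]:
        """Means rounded to 2 decimals, as exported in the JSON summary."""
        out: dict[str, float | int] = {"rows": len(self.rows)}
        if self.rows:
            out.update(
                mean_dai=round(self.mean_dai, 2),
                mean_nsi=round(self.mean_nsi, 2),
                mean_np=round(self.mean_np, 2),
            )
        return out
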