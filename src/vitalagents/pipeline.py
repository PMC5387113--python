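"""End-to-end monitoring workflow: detection, notification, delay telemetry.

A **monitoring agent** (ticker behavior) periodically retrieves the new
readings of every patient from the store (stamping T1 once per tick),
runs the rule engine on each, and emits one message per anomaly (stamping
T2).  A **notification agent** (one-shot behavior) receives each anomaly,
starts the routine (T3), dispatches through a channel adapter (T4 on
send), and records the adapter's receipt acknowledgment (T5, at minute
resolution — phones do not report SMS receipt with second precision).

Four intervals summarise responsiveness per notification:

    DAI = T2 − T1    detection delay within the monitoring routine
    NSI = T3 − T2    handoff from detection to the notification routine
    NP  = T4 − T3    duration of the notification routine
    NRI = T5 − T4    transit time, known only as a bound (coarse T5)

Channel adapters are stubs with configurable simulated latency so the
full telemetry can be exercised without any real SMS/email backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    AnomalyEvent,
    Channel,
    DelayReport,
    DelayRow,
    Instant,
    NotificationRecord,
    NotificationRoute,
    Reading,
    format_timestamp,
    interval_seconds,
    parse_timestamp,
)
from .errors import ChannelError, OrderingError, StoreUnavailableError, VitalAgentsError
from .knowledge_base import KnowledgeBase, effective_rules
from .rules import (
    Classification,
    ContextAdjustTable,
    DEFAULT_ADJUST_TABLE,
    Status,
    evaluate_reading,
)
from .runtime import AgentSpec, Behavior, BehaviorKind, Scheduler
from .storage import PatientRegistry, ReadingStore

__all__ = [
    "ChannelAdapter",
    "ConsoleChannel",
    "SimulatedSmsChannel",
    "default_channel_adapters",
    "PipelineConfig",
    "monitor_step",
    "notify",
    "compute_delays",
    "delay_report_frame",
    "write_notifications_csv",
    "read_notifications_csv",
    "recompute_intervals",
    "MonitoringSession",
    "SessionResult",
]

logger = logging.getLogger(__name__)

TELEMETRY_COLUMNS = ["T1", "T2", "T3", "T4", "T5", "DAI", "NSI", "NP"]


# ---------------------------------------------------------------------------
# Channel adapters
# ---------------------------------------------------------------------------


class ChannelAdapter:
    """Stub delivery channel with simulated latencies (seconds).

    ``send_latency`` separates routine start (T3) from message send (T4);
    ``receipt_latency`` separates send from receipt (T5), reported at
    minute resolution.  ``receipt_latency=None`` means the channel gives
    no receipt signal (T5 absent).
    """

    channel: Channel = Channel.CONSOLE

    def __init__(self, send_latency: int = 0, receipt_latency: int | None = 0):
        if send_latency < 0 or (receipt_latency is not None and receipt_latency < 0):
            raise VitalAgentsError("channel latencies must be >= 0")
        self.send_latency = send_latency
        self.receipt_latency = receipt_latency

    def dispatch(self, event: AnomalyEvent, route: NotificationRoute) -> tuple[int, int | None]:
        """Attempt delivery; returns (send_latency, receipt_latency).

        Raises :class:`ChannelError` on a (simulated) transient failure.
        """
        return self.send_latency, self.receipt_latency


class ConsoleChannel(ChannelAdapter):
    """Zero-latency local channel: T4 = T3, receipt immediate."""

    channel = Channel.CONSOLE


class SimulatedSmsChannel(ChannelAdapter):
    """SMS stand-in: a couple of seconds to send, sub-minute receipt.

    ``fail_times`` makes the first n dispatch attempts raise, to exercise
    the retry policy.
    """

    channel = Channel.SMS

    def __init__(self, send_latency: int = 2, receipt_latency: int | None = 45, fail_times: int = 0):
        super().__init__(send_latency, receipt_latency)
        self._fail_remaining = fail_times

    def dispatch(self, event, route):
        if self._fail_remaining > 0:
            self._fail_remaining -= 1
            raise ChannelError(f"simulated SMS gateway failure for {route.address!r}")
        return super().dispatch(event, route)


def default_channel_adapters() -> dict[Channel, ChannelAdapter]:
    sms = SimulatedSmsChannel()
    return {
        Channel.CONSOLE: ConsoleChannel(),
        Channel.SMS: sms,
        Channel.EMAIL: SimulatedSmsChannel(send_latency=1, receipt_latency=30),
        Channel.VOICE: sms,
        Channel.BLUETOOTH: ConsoleChannel(),
    }


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Study conditions for one simulated monitoring run.

    ``retrieval_latency`` and ``classify_latency`` model the time the
    monitoring agent spends fetching and analysing a batch within one tick
    (their sum is the DAI of every detection) and must fit inside the
    ticker period — an analysis that outlasts its tick would fall behind
    the stream.  ``delivery_latency`` is the message-bus handoff (0 by
    default: detection and routine start share the tick, so NSI = 0).
    """

    ticker_period: int = 6
    retrieval_latency: int = 2
    classify_latency: int = 1
    delivery_latency: int = 0
    quality_gate_enabled: bool = True
    adjust_table: ContextAdjustTable = field(default_factory=lambda: DEFAULT_ADJUST_TABLE)
    retry_attempts: int = 3
    channels: dict[Channel, ChannelAdapter] = field(default_factory=default_channel_adapters)

    def __post_init__(self) -> None:
        if self.ticker_period <= 0:
            raise VitalAgentsError("ticker_period must be > 0")
        if self.retrieval_latency < 0 or self.classify_latency < 0 or self.delivery_latency < 0:
            raise VitalAgentsError("latencies must be >= 0")
        if self.retrieval_latency + self.classify_latency > self.ticker_period:
            raise VitalAgentsError(
                "retrieval + classification latency must fit within one ticker period "
                f"({self.retrieval_latency}+{self.classify_latency} > {self.ticker_period})"
            )


# ---------------------------------------------------------------------------
# Monitoring step (T1, T2)
# ---------------------------------------------------------------------------


@dataclass
class SuppressedReading:
    reading: Reading
    classification: Classification


def monitor_step(
    registry: PatientRegistry,
    store: ReadingStore,
    kb: KnowledgeBase,
    *,
    now: Instant,
    high_water: dict[tuple[str, str], Instant],
    config: PipelineConfig,
) -> tuple[list[AnomalyEvent], list[SuppressedReading]]:
    """One monitoring tick: retrieve, gate, adjust, classify.

    T1 is stamped once for the tick (batch retrieval); every anomaly in
    the batch gets T2 = T1 + retrieval latency + classification latency.
    ``high_water`` (mutated in place) holds the newest processed timestamp
    per (patient, sensor) stream so no reading is ever re-processed.
    A store outage skips the tick without crashing; the untouched
    high-water mark makes the next tick retry the same window.
    """
    t1 = now
    t2 = t1.plus(config.retrieval_latency + config.classify_latency)
    events: list[AnomalyEvent] = []
    suppressed: list[SuppressedReading] = []
    for pid, patient in registry.patients.items():
        try:
            new_readings = store.query(patient_id=pid, t_to=now.plus(1))
        except StoreUnavailableError as exc:
            logger.warning("monitor tick skipped for %s: %s", pid, exc)
            continue
        for reading in new_readings:
            stream = (pid, reading.sensor_id)
            mark = high_water.get(stream)
            if mark is not None and not mark < reading.timestamp:
                continue
            high_water[stream] = reading.timestamp
            entry = effective_rules(kb, patient, reading.modality)
            result = evaluate_reading(
                reading,
                entry,
                quality_gate_enabled=config.quality_gate_enabled,
                adjust_table=config.adjust_table,
            )
            if result.status is Status.ANOMALOUS:
                events.append(AnomalyEvent(reading=reading, label=result.label, t1=t1, t2=t2))
            elif result.status is not Status.NORMAL:
                suppressed.append(SuppressedReading(reading=reading, classification=result))
    return events, suppressed


# ---------------------------------------------------------------------------
# Notification step (T3, T4, T5)
# ---------------------------------------------------------------------------


def notify(
    event: AnomalyEvent,
    routes: tuple[NotificationRoute, ...],
    *,
    t3: Instant,
    adapters: dict[Channel, ChannelAdapter],
    retry_attempts: int = 3,
) -> tuple[list[NotificationRecord], list[dict]]:
    """Dispatch one anomaly over every configured route (fan-out).

    One record per (event, route).  A failing channel is retried up to
    ``retry_attempts`` times; exhausted retries yield a failure entry
    instead of a record.
    """
    records: list[NotificationRecord] = []
    failures: list[dict] = []
    for route in routes:
        adapter = adapters.get(route.channel)
        if adapter is None:
            failures.append({"route": route, "error": f"no adapter for {route.channel.value}"})
            continue
        last_error: str | None = None
        for _ in range(max(1, retry_attempts)):
            try:
                send_latency, receipt_latency = adapter.dispatch(event, route)
            except ChannelError as exc:
                last_error = str(exc)
                continue
            t4 = t3.plus(send_latency)
            t5 = t4.plus(receipt_latency).floor_minute() if receipt_latency is not None else None
            records.append(NotificationRecord(event=event, route=route, t3=t3, t4=t4, t5=t5))
            last_error = None
            break
        if last_error is not None:
            logger.error("notification failed after retries: %s", last_error)
            failures.append({"route": route, "error": last_error})
    return records, failures


# ---------------------------------------------------------------------------
# Delay telemetry
# ---------------------------------------------------------------------------


def _nri_bounds(t4: Instant, t5: Instant | None) -> tuple[int | None, int | None]:
    if t5 is None:
        return None, None
    offset = int((t5.dt - t4.dt).total_seconds())
    return max(0, offset), offset + 59  # true receipt lies within T5's minute


def compute_delays(records: list[NotificationRecord]) -> DelayReport:
    """DAI/NSI/NP per record (exact integer seconds) plus NRI bounds.

    Non-monotone timestamps raise :class:`OrderingError` naming the record.
    """
    rows: list[DelayRow] = []
    for i, rec in enumerate(records):
        try:
            dai = interval_seconds(rec.event.t1, rec.event.t2)
            nsi = interval_seconds(rec.event.t2, rec.t3)
            np_ = interval_seconds(rec.t3, rec.t4)
        except OrderingError as exc:
            raise OrderingError(f"record #{i + 1} ({rec.event.label}): {exc}") from exc
        lo, hi = _nri_bounds(rec.t4, rec.t5)
        rows.append(DelayRow(record=rec, dai=dai, nsi=nsi, np=np_, nri_lower=lo, nri_upper=hi))
    return DelayReport(rows=tuple(rows))


def delay_report_frame(report: DelayReport) -> pd.DataFrame:
    """Delay report as a DataFrame in the telemetry CSV layout."""
    data = []
    for row in report.rows:
        rec = row.record
        data.append(
            {
                "T1": format_timestamp(rec.event.t1),
                "T2": format_timestamp(rec.event.t2),
                "T3": format_timestamp(rec.t3),
                "T4": format_timestamp(rec.t4),
                "T5": format_timestamp(rec.t5) if rec.t5 is not None else "",
                "DAI": row.dai,
                "NSI": row.nsi,
                "NP": row.np,
            }
        )
    return pd.DataFrame(data, columns=TELEMETRY_COLUMNS)


def write_notifications_csv(report: DelayReport, path) -> None:
    delay_report_frame(report).to_csv(path, index=False)


def read_notifications_csv(path) -> pd.DataFrame:
    """Read a telemetry CSV, raising a parse error with the line number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ["T1", "T2", "T3", "T4"] if c not in df.columns]
    if missing:
        raise VitalAgentsError(f"{path}: telemetry CSV missing columns {missing}")
    return df


def recompute_intervals(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Recompute DAI/NSI/NP from the timestamp columns of a telemetry table.

    Returns the table with recomputed interval columns (and NRI bounds when
    T5 is present) plus a list of mismatch messages where pre-filled
    interval columns disagree with the timestamps.
    """
    out = df.copy()
    mismatches: list[str] = []
    dai_col, nsi_col, np_col, nlo, nhi = [], [], [], [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            t1, t2 = parse_timestamp(row["T1"]), parse_timestamp(row["T2"])
            t3, t4 = parse_timestamp(row["T3"]), parse_timestamp(row["T4"])
            dai = interval_seconds(t1, t2)
            nsi = interval_seconds(t2, t3)
            np_ = interval_seconds(t3, t4)
        except (OrderingError, VitalAgentsError) as exc:
            raise OrderingError(f"line {line}: {exc}") from exc
        t5_text = str(row.get("T5", "") or "").strip()
        if t5_text:
            lo, hi = _nri_bounds(t4, parse_timestamp(t5_text).floor_minute())
        else:
            lo = hi = None
        for name, recomputed in (("DAI", dai), ("NSI", nsi), ("NP", np_)):
            stated = str(row.get(name, "") or "").strip()
            if stated and int(float(stated)) != recomputed:
                mismatches.append(
                    f"line {line}: {name} stated {stated} but timestamps give {recomputed}"
                )
        dai_col.append(dai)
        nsi_col.append(nsi)
        np_col.append(np_)
        nlo.append(lo)
        nhi.append(hi)
    out["DAI"], out["NSI"], out["NP"] = dai_col, nsi_col, np_col
    out["NRI_lower"], out["NRI_upper"] = nlo, nhi
    return out, mismatches


# ---------------------------------------------------------------------------
# Session wiring
# ---------------------------------------------------------------------------


@dataclass
class SessionResult:
    """Everything one simulated run produced."""

    events: list[AnomalyEvent]
    records: list[NotificationRecord]
    suppressed: list[SuppressedReading]
    unrouted: list[AnomalyEvent]
    failures: list[dict]
    event_log_text: str

    def delay_report(self) -> DelayReport:
        return compute_delays(self.records)


class MonitoringSession:
    """Wires monitoring and notification agents onto the scheduler.

    The monitoring agent is a ticker with the configured period; the
    notification agent is a one-shot triggered per anomaly message.
    Anomalies whose label has no route are parked in an explicit unrouted
    queue (a monitoring system must not crash on a configuration gap).
    """

    def __init__(
        self,
        kb: KnowledgeBase,
        store: ReadingStore,
        registry: PatientRegistry,
        config: PipelineConfig | None = None,
        epoch=None,
    ):
        from .core import DEFAULT_EPOCH

        self.kb = kb
        self.store = store
        self.registry = registry
        self.config = config or PipelineConfig()
        self.scheduler = Scheduler(
            epoch=epoch or DEFAULT_EPOCH,
            delivery_latency=self.config.delivery_latency,
        )
        self.high_water: dict[tuple[str, str], Instant] = {}
        self.events: list[AnomalyEvent] = []
        self.records: list[NotificationRecord] = []
        self.suppressed: list[SuppressedReading] = []
        self.unrouted: list[AnomalyEvent] = []
        self.failures: list[dict] = []
        self._register_agents()

    def _register_agents(self) -> None:
        cfg = self.config

        def monitor_action(ctx, _msg):
            events, suppressed = monitor_step(
                self.registry,
                self.store,
                self.kb,
                now=ctx.instant(),
                high_water=self.high_water,
                config=cfg,
            )
            self.suppressed.extend(suppressed)
            t2_seconds = ctx.now + cfg.retrieval_latency + cfg.classify_latency
            for event in events:
                self.events.append(event)
                ctx.send("notifier", event, sent_at=t2_seconds)

        def notify_action(ctx, msg):
            event: AnomalyEvent = msg.payload
            routes = self.kb.routes.get(event.label)
            if not routes:
                logger.warning("alerting gap: no route for label %r", event.label)
                self.unrouted.append(event)
                return
            records, failures = notify(
                event,
                routes,
                t3=ctx.instant(),
                adapters=cfg.channels,
                retry_attempts=cfg.retry_attempts,
            )
            self.records.extend(records)
            self.failures.extend(failures)

        self.scheduler.register_agent(
            AgentSpec(
                agent_id="monitor",
                behaviors=(
                    Behavior(
                        kind=BehaviorKind.TICKER,
                        action=monitor_action,
                        period=cfg.ticker_period,
                        name="monitor_step",
                    ),
                ),
            )
        )
        self.scheduler.register_agent(
            AgentSpec(
                agent_id="notifier",
                behaviors=(
                    Behavior(kind=BehaviorKind.ONE_SHOT, action=notify_action, name="notify"),
                ),
            )
        )

    def run(self, t_end: int) -> SessionResult:
        self.scheduler.run_until(t_end)
        return SessionResult(
            events=self.events,
            records=self.records,
            suppressed=self.suppressed,
            unrouted=self.unrouted,
            failures=self.failures,
            event_log_text=self.scheduler.export_event_log(),
        )
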