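"""Minimal deterministic agent scheduler and message bus.

Agents carry two behaviour kinds, mirroring the classic agent-middleware
pattern: a **ticker** runs cyclically at a fixed period (continuous
monitoring), a **one-shot** runs once per triggering message (on-demand
notification dispatch).  The scheduler is a single-threaded discrete-event
loop over a simulated clock at one-second resolution; concurrency is
modeled, not real, and the contract is the event ordering below.

Ordering rules:

* a ticker registered at time t0 with period p fires at t0, t0+p, t0+2p, …
  (``run_until(t_end)`` therefore yields ⌊(t_end−t0)/p⌋+1 firings);
* messages between one sender–receiver pair are delivered in send order,
  exactly once, after a configurable delivery latency (default 0 s);
* simultaneous events are ordered by (agent registration order, behavior
  index, global sequence number) — fully reproducible;
* a message to an unregistered receiver goes to the dead-letter log, never
  silently dropped.

Identical (configuration, stream, seed) inputs produce byte-identical
event logs.
"""

from __future__ import annotations

import enum
import hashlib
import heapq
import itertools
import json
from dataclasses import dataclass, field
from typing import Any, Callable

from .core import DEFAULT_EPOCH, Instant
from .errors import IntegrityError, VitalAgentsError

__all__ = [
    "BehaviorKind",
    "Behavior",
    "AgentSpec",
    "Performative",
    "Message",
    "Scheduler",
    "AgentContext",
]


class BehaviorKind(str, enum.Enum):
    TICKER = "ticker"
    ONE_SHOT = "one_shot"


class Performative(str, enum.Enum):
    INFORM = "inform"
    REQUEST = "request"


@dataclass(frozen=True)
class Behavior:
    """One agent behavior: cyclic (ticker) or message-triggered (one-shot)."""

    kind: BehaviorKind
    action: Callable[["AgentContext", "Message | None"], None]
    period: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind is BehaviorKind.TICKER:
            if self.period is None or self.period <= 0:
                raise VitalAgentsError("ticker behavior requires period > 0")
        elif self.period is not None:
            raise VitalAgentsError("one-shot behavior must not carry a period")


@dataclass(frozen=True)
class AgentSpec:
    agent_id: str
    behaviors: tuple[Behavior, ...]

    def __post_init__(self) -> None:
        if not self.agent_id:
            raise VitalAgentsError("agent_id must be non-empty")
        if not self.behaviors:
            raise VitalAgentsError(f"agent {self.agent_id!r} has no behaviors")


@dataclass(frozen=True)
class Message:
    sender: str
    receiver: str
    performative: Performative
    payload: Any
    sent_at: int


def _digest(payload: Any) -> str:
    """Stable short digest of a payload for the event log."""
    text = repr(payload)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class AgentContext:
    """Handle passed to behavior actions: clock access and message sending."""

    scheduler: "Scheduler"
    agent_id: str

    @property
    def now(self) -> int:
        return self.scheduler.now

    def instant(self, at: int | None = None) -> Instant:
        return self.scheduler.instant(at)

    def send(
        self,
        receiver: str,
        payload: Any,
        performative: Performative = Performative.INFORM,
        sent_at: int | None = None,
    ) -> Message:
        msg = Message(
            sender=self.agent_id,
            receiver=receiver,
            performative=performative,
            payload=payload,
            sent_at=self.scheduler.now if sent_at is None else int(sent_at),
        )
        self.scheduler.send(msg)
        return msg


@dataclass
class _RegisteredAgent:
    spec: AgentSpec
    index: int  # registration order, first tie-break component


class Scheduler:
    """Discrete-event loop driving agents on a simulated clock.

    Parameters
    ----------
    start_time:
        Initial simulated time in seconds.
    epoch:
        Calendar instant corresponding to simulated second 0, used when
        stamping telemetry.
    delivery_latency:
        Simulated seconds between message send and delivery (default 0:
        same-tick handoff).
    first_fire_immediately:
        If True (default), a ticker's first firing is at registration time
        t0; if False it waits one period (the middleware-style convention).
    """

    def __init__(
        self,
        start_time: int = 0,
        epoch=DEFAULT_EPOCH,
        delivery_latency: int = 0,
        first_fire_immediately: bool = True,
    ):
        if delivery_latency < 0:
            raise VitalAgentsError("delivery_latency must be >= 0")
        self.now = int(start_time)
        self.epoch = epoch
        self.delivery_latency = int(delivery_latency)
        self.first_fire_immediately = first_fire_immediately
        self._agents: dict[str, _RegisteredAgent] = {}
        self._seq = itertools.count()
        # heap entries: (time, agent_index, behavior_index, seq, kind, payload)
        self._queue: list[tuple[int, int, int, int, str, Any]] = []
        self.event_log: list[dict[str, Any]] = []
        self.dead_letters: list[Message] = []

    # -- registration ------------------------------------------------------

    def register_agent(self, spec: AgentSpec) -> AgentContext:
        if spec.agent_id in self._agents:
            raise IntegrityError(f"duplicate agent id {spec.agent_id!r}")
        agent = _RegisteredAgent(spec=spec, index=len(self._agents))
        self._agents[spec.agent_id] = agent
        for b_idx, behavior in enumerate(spec.behaviors):
            if behavior.kind is BehaviorKind.TICKER:
                first = self.now if self.first_fire_immediately else self.now + behavior.period
                heapq.heappush(
                    self._queue,
                    (first, agent.index, b_idx, next(self._seq), "tick", None),
                )
        return AgentContext(scheduler=self, agent_id=spec.agent_id)

    # -- messaging ---------------------------------------------------------

    def send(self, msg: Message) -> dict[str, Any]:
        """Queue a message for delivery; unknown receivers are dead-lettered."""
        receiver = self._agents.get(msg.receiver)
        if receiver is None:
            self.dead_letters.append(msg)
            receipt = {"status": "dead_letter", "receiver": msg.receiver}
            self._log("dead_letter", msg.sender, t=max(self.now, msg.sent_at), payload=msg.payload)
            return receipt
        deliver_at = max(self.now, msg.sent_at) + self.delivery_latency
        for b_idx, behavior in enumerate(receiver.spec.behaviors):
            if behavior.kind is BehaviorKind.ONE_SHOT:
                heapq.heappush(
                    self._queue,
                    (deliver_at, receiver.index, b_idx, next(self._seq), "deliver", msg),
                )
        self._log("send", msg.sender, t=max(self.now, msg.sent_at), payload=msg.payload)
        return {"status": "queued", "deliver_at": deliver_at}

    # -- clock -------------------------------------------------------------

    def instant(self, at: int | None = None) -> Instant:
        from datetime import timedelta

        t = self.now if at is None else int(at)
        return Instant(self.epoch + timedelta(seconds=t))

    # -- main loop ---------------------------------------------------------

    def run_until(self, t_end: int) -> list[dict[str, Any]]:
        """Process every event with time ≤ t_end; returns the event log.

        Events beyond ``t_end`` remain queued, so the loop can be resumed.
        """
        agents_by_index = {a.index: a for a in self._agents.values()}
        while self._queue and self._queue[0][0] <= t_end:
            t, a_idx, b_idx, _seq, kind, payload = heapq.heappop(self._queue)
            self.now = max(self.now, t)
            agent = agents_by_index[a_idx]
            behavior = agent.spec.behaviors[b_idx]
            ctx = AgentContext(scheduler=self, agent_id=agent.spec.agent_id)
            if kind == "tick":
                self._log("tick", agent.spec.agent_id, behavior=behavior.name or f"b{b_idx}")
                behavior.action(ctx, None)
                heapq.heappush(
                    self._queue,
                    (t + behavior.period, a_idx, b_idx, next(self._seq), "tick", None),
                )
            else:  # deliver
                msg: Message = payload
                self._log(
                    "deliver",
                    agent.spec.agent_id,
                    behavior=behavior.name or f"b{b_idx}",
                    payload=msg.payload,
                )
                behavior.action(ctx, msg)
        self.now = max(self.now, t_end)
        return self.event_log

    # -- logging -----------------------------------------------------------

    def _log(self, kind: str, agent: str, t: int | None = None, **extra: Any) -> None:
        entry: dict[str, Any] = {"t": self.now if t is None else t, "kind": kind, "agent": agent}
        if "payload" in extra:
            entry["payload_digest"] = _digest(extra.pop("payload"))
        entry.update(extra)
        self.event_log.append(entry)

    def export_event_log(self) -> str:
        """JSON-lines event log, byte-identical across identical runs."""
        return "".join(json.dumps(e, sort_keys=True) + "\n" for e in self.event_log)
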