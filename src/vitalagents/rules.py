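"""Classification of readings against effective rules, with false-alarm
suppression and dynamic reconfiguration.

Two false-alarm strategies, both configurable:

* a **signal-quality gate** — readings whose sensor self-reports unreliable
  contact (``poor`` or ``missing`` quality) are suppressed before any
  classification, never alerted;
* **context adjustment** — during physical activity (accelerometer
  context) the heart-rate DVR's high bound is widened by a configured
  amount so exercise tachycardia is not flagged.

A reading exactly at a DVR bound is normal; anomalies are the strict
complement (value < low or value > high).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .core import Activity, AnomalyRule, DesiredValueRange, Modality, Reading, Side, SignalQuality
from .knowledge_base import KnowledgeBase, RuleEntry
from .errors import VitalAgentsError

__all__ = [
    "Status",
    "Classification",
    "ContextAdjustTable",
    "DEFAULT_ADJUST_TABLE",
    "classify",
    "quality_gate",
    "context_adjust",
    "evaluate_reading",
    "reconfigure",
]

logger = logging.getLogger(__name__)


class Status(str, enum.Enum):
    NORMAL = "normal"
    ANOMALOUS = "anomalous"
    SUPPRESSED_QUALITY = "suppressed_quality"
    SUPPRESSED_CONTEXT = "suppressed_context"


@dataclass(frozen=True)
class Classification:
    """Outcome of evaluating one reading.

    ``label`` and ``rule_used`` are set iff the status is anomalous;
    suppressed statuses carry a human-readable ``reason`` for the audit log.
    """

    status: Status
    label: str | None = None
    rule_used: AnomalyRule | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if (self.status is Status.ANOMALOUS) != (self.label is not None):
            raise ValueError("label must be present iff status is anomalous")


@dataclass(frozen=True)
class ContextAdjustTable:
    """Additive DVR widening applied per modality during activity.

    ``widen_high`` maps a modality to the number of units added to the DVR
    high bound while the patient is active.  The default widens heart rate
    by 40 bpm and leaves every other modality untouched; the table is
    configuration, not code.
    """

    widen_high: Mapping[Modality, float] = field(
        default_factory=lambda: MappingProxyType({Modality.HEART_RATE: 40.0})
    )

    def __post_init__(self) -> None:
        for modality, amount in self.widen_high.items():
            if amount < 0:
                raise VitalAgentsError(
                    f"negative context widening for {modality.value}: {amount}"
                )


DEFAULT_ADJUST_TABLE = ContextAdjustTable()


def classify(
    reading: Reading,
    dvr: DesiredValueRange,
    rules: tuple[AnomalyRule, ...],
) -> Classification:
    """Trichotomy: normal, below-low anomaly, or above-high anomaly.

    Bounds are inclusive for normal; exactly one branch fires for any
    finite value.
    """
    if dvr.contains(reading.value):
        return Classification(status=Status.NORMAL)
    side = Side.BELOW_LOW if reading.value < dvr.low else Side.ABOVE_HIGH
    rule = next(r for r in rules if r.side is side)
    return Classification(status=Status.ANOMALOUS, label=rule.label, rule_used=rule)


def quality_gate(reading: Reading, enabled: bool = True) -> bool:
    """True iff the reading passes the signal-quality gate.

    With the gate enabled, any reading whose quality is not ``good`` is
    ignored until the signal becomes reliable again; disabling the gate
    lets everything through.
    """
    if not enabled:
        return True
    return reading.signal_quality is SignalQuality.GOOD


def context_adjust(
    dvr: DesiredValueRange,
    modality: Modality,
    activity: Activity,
    table: ContextAdjustTable = DEFAULT_ADJUST_TABLE,
) -> DesiredValueRange:
    """Widen the DVR high bound during activity, per the adjustment table.

    Identity for rest/unknown activity and for modalities absent from the
    table (temperature is never widened by the default table).
    """
    if activity is not Activity.ACTIVE:
        return dvr
    amount = table.widen_high.get(modality)
    if not amount:
        return dvr
    return DesiredValueRange(low=dvr.low, high=dvr.high + amount)


def evaluate_reading(
    reading: Reading,
    entry: RuleEntry,
    *,
    quality_gate_enabled: bool = True,
    adjust_table: ContextAdjustTable = DEFAULT_ADJUST_TABLE,
) -> Classification:
    """Full evaluation: quality gate → context adjustment → classification.

    Quality suppression wins over everything (a gated reading is never
    classified).  A reading anomalous under the raw DVR but normal under
    the activity-widened DVR is reported as context-suppressed, so audits
    can distinguish "normal" from "excused by exercise".
    """
    if not quality_gate(reading, enabled=quality_gate_enabled):
        return Classification(
            status=Status.SUPPRESSED_QUALITY,
            reason=f"signal quality {reading.signal_quality.value}",
        )
    adjusted = context_adjust(entry.dvr, reading.modality, reading.activity, adjust_table)
    result = classify(reading, adjusted, entry.rules)
    if result.status is Status.ANOMALOUS:
        return result
    if adjusted != entry.dvr and not entry.dvr.contains(reading.value):
        return Classification(
            status=Status.SUPPRESSED_CONTEXT,
            reason=f"within activity-widened range during {reading.activity.value}",
        )
    return result


def reconfigure(kb: KnowledgeBase, patient_id: str, new_context: str) -> KnowledgeBase:
    """Move a patient to a new monitoring context (e.g. a room change).

    Returns a *new* knowledge base whose rule resolution for the patient
    uses ``new_context``; the original is untouched, so a classification
    batch holding the old object never sees a half-applied change — callers
    swap at a batch boundary.  The change is logged with before/after.

    Raises :class:`UnknownContextError` (knowledge base unchanged) if
    ``new_context`` is not a context key of the configuration.
    """
    before = kb.patient_contexts.get(patient_id)
    updated = kb.with_patient_context(patient_id, new_context)
    logger.info(
        "reconfigure patient=%s context: %s -> %s", patient_id, before, new_context
    )
    return updated
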