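"""Bundled example configuration and telemetry.

The example knowledge base carries the canonical textbook thresholds used
throughout the documentation and tests: heart rate normal in 60–110 bpm
(below → Bradyarrhythmias, above → Tachyarrhythmias) and body temperature
normal in 36.0–36.6 °C (below → Hypothermia, above → Hyperthermia).

``EXAMPLE_TELEMETRY_ROWS`` is a small published trace of six notification
cycles from a bedside telemonitoring experiment, in the telemetry CSV
dialect; it exercises the interval arithmetic (including a minute
rollover) and anchors the worked example in the README.
"""

from __future__ import annotations

from .core import AnomalyRule, Channel, DesiredValueRange, Modality, NotificationRoute, Side
from .knowledge_base import DEFAULT_PATIENT, KnowledgeBase, RuleEntry

__all__ = ["example_knowledge_base", "EXAMPLE_TELEMETRY_ROWS", "EXAMPLE_TELEMETRY_CSV"]


def example_knowledge_base(routes: bool = True) -> KnowledgeBase:
    """Knowledge base with the example heart-rate and temperature rules."""
    entries = {
        (DEFAULT_PATIENT, Modality.HEART_RATE, None): RuleEntry(
            dvr=DesiredValueRange(low=60.0, high=110.0),
            rules=(
                AnomalyRule(side=Side.BELOW_LOW, label="Bradyarrhythmias"),
                AnomalyRule(side=Side.ABOVE_HIGH, label="Tachyarrhythmias"),
            ),
        ),
        (DEFAULT_PATIENT, Modality.BODY_TEMPERATURE, None): RuleEntry(
            dvr=DesiredValueRange(low=36.0, high=36.6),
            rules=(
                AnomalyRule(side=Side.BELOW_LOW, label="Hypothermia"),
                AnomalyRule(side=Side.ABOVE_HIGH, label="Hyperthermia"),
            ),
        ),
    }
    route_table: dict[str, tuple[NotificationRoute, ...]] = {}
    unrouted: frozenset[str] = frozenset()
    labels = ["Bradyarrhythmias", "Tachyarrhythmias", "Hypothermia", "Hyperthermia"]
    if routes:
        route_table = {
            label: (
                NotificationRoute(
                    label=label,
                    provider_id="on-call",
                    channel=Channel.SMS,
                    address="+550000000000",
                ),
            )
            for label in labels
        }
    else:
        unrouted = frozenset(labels)
    return KnowledgeBase(entries=entries, routes=route_table, unrouted=unrouted)


#: Six notification cycles (T1–T5 plus stated DAI/NSI/NP), including a
#: minute rollover in row 5.  T5 is minute-resolution, as phones report it.
EXAMPLE_TELEMETRY_ROWS: list[dict[str, str]] = [
    {"T1": "2016-11-04-173424", "T2": "2016-11-04-173427", "T3": "2016-11-04-173427",
     "T4": "2016-11-04-173428", "T5": "2016-11-04-1734", "DAI": "3", "NSI": "0", "NP": "1"},
    {"T1": "2016-11-04-173430", "T2": "2016-11-04-173434", "T3": "2016-11-04-173434",
     "T4": "2016-11-04-173436", "T5": "2016-11-04-1735", "DAI": "4", "NSI": "0", "NP": "2"},
    {"T1": "2016-11-04-173442", "T2": "2016-11-04-173445", "T3": "2016-11-04-173445",
     "T4": "2016-11-04-173448", "T5": "2016-11-04-1735", "DAI": "3", "NSI": "0", "NP": "3"},
    {"T1": "2016-11-04-173450", "T2": "2016-11-04-173454", "T3": "2016-11-04-173454",
     "T4": "2016-11-04-173455", "T5": "2016-11-04-1735", "DAI": "4", "NSI": "0", "NP": "1"},
    {"T1": "2016-11-04-173458", "T2": "2016-11-04-173501", "T3": "2016-11-04-173501",
     "T4": "2016-11-04-173502", "T5": "2016-11-04-1735", "DAI": "3", "NSI": "0", "NP": "1"},
    {"T1": "2016-11-04-173504", "T2": "2016-11-04-173507", "T3": "2016-11-04-173507",
     "T4": "2016-11-04-173509", "T5": "2016-11-04-1735", "DAI": "3", "NSI": "0", "NP": "2"},
]

EXAMPLE_TELEMETRY_CSV = "T1,T2,T3,T4,T5,DAI,NSI,NP\n" + "\n".join(
    ",".join(row[c] for c in ["T1", "T2", "T3", "T4", "T5", "DAI", "NSI", "NP"])
    for row in EXAMPLE_TELEMETRY_ROWS
) + "\n"
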