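"""The agents' knowledge base: monitoring rules and notification routes.

Domain specialists configure, per patient and sensor, a desired value range
(DVR) and the two labelled anomaly rules covering its complement, plus a
routing table mapping each anomaly label to the providers and channels that
must be alerted.  The whole configuration lives in one XML document:

.. code-block:: xml

    <knowledgeBase version="1" author="ward-admin">
      <patients>
        <patient id="default">
          <sensor modality="body_temperature" unit="degC">
            <dvr low="36.0" high="36.6"/>
            <anomaly side="below_low" label="Hypothermia"/>
            <anomaly side="above_high" label="Hyperthermia"/>
          </sensor>
        </patient>
      </patients>
      <routes>
        <route label="Hyperthermia" provider="drA" channel="sms" address="+5500000000"/>
      </routes>
      <unrouted/>
    </knowledgeBase>

``patient id="default"`` holds modality defaults; a ``context`` attribute on
``<sensor>`` scopes an entry to a ward/room context key.  Validation is
eager and exhaustive: every problem in the document is reported at once.
A JSON mirror of the same structure is accepted for files ending ``.json``.

XML external entities are never resolved (the stdlib parser does not expand
them), and no DTD processing occurs.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

from .core import AnomalyRule, Channel, DesiredValueRange, Modality, NotificationRoute, PatientProfile, Side
from .errors import ConfigurationMissingError, IntegrityError, UnknownContextError, ValidationError

__all__ = [
    "DEFAULT_PATIENT",
    "RuleEntry",
    "KnowledgeBase",
    "load_knowledge_base",
    "save_knowledge_base",
    "effective_rules",
]

logger = logging.getLogger(__name__)

#: Sentinel patient id holding modality defaults.
DEFAULT_PATIENT = "default"


@dataclass(frozen=True)
class RuleEntry:
    """A DVR plus the two anomaly rules covering its complement."""

    dvr: DesiredValueRange
    rules: tuple[AnomalyRule, AnomalyRule]

    def __post_init__(self) -> None:
        sides = {r.side for r in self.rules}
        if sides != {Side.BELOW_LOW, Side.ABOVE_HIGH}:
            raise ValueError("a rule entry needs exactly one rule per side of the DVR")
        labels = {r.label for r in self.rules}
        if len(labels) != 2:
            raise ValueError("the two anomaly rules must carry distinct labels")
        # canonical order (below_low, above_high) so equality ignores input order
        object.__setattr__(
            self, "rules", tuple(sorted(self.rules, key=lambda r: r.side is Side.ABOVE_HIGH))
        )

    def rule_for(self, side: Side) -> AnomalyRule:
        return next(r for r in self.rules if r.side is side)


#: (patient_id or "default", modality, context key or None)
Key = tuple[str, Modality, str | None]


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated monitoring configuration.

    ``entries`` maps (patient, modality, context) keys to rule entries;
    ``routes`` maps anomaly labels to their notification routes; labels
    deliberately left without a route must appear in ``unrouted``.
    ``patient_contexts`` holds administrative context overrides applied by
    :func:`vitalagents.rules.reconfigure` (e.g. after a room change).
    """

    entries: dict[Key, RuleEntry] = field(default_factory=dict)
    routes: dict[str, tuple[NotificationRoute, ...]] = field(default_factory=dict)
    unrouted: frozenset[str] = frozenset()
    version: str = "1"
    author: str = ""
    patient_contexts: dict[str, str] = field(default_factory=dict)

    # -- introspection -----------------------------------------------------

    def labels(self) -> set[str]:
        return {r.label for e in self.entries.values() for r in e.rules}

    def contexts(self) -> set[str]:
        """Context keys known to this configuration."""
        return {c for (_, _, c) in self.entries if c is not None}

    def problems(self) -> list[str]:
        """Every invariant violation in this knowledge base (empty if valid)."""
        out: list[str] = []
        for label in sorted(self.labels()):
            if label not in self.routes and label not in self.unrouted:
                out.append(
                    f"label {label!r} has no notification route and is not marked unrouted"
                )
        for label, routes in self.routes.items():
            pairs = [(r.label, r.provider_id) for r in routes]
            if len(pairs) != len(set(pairs)):
                out.append(f"duplicate (label, provider) route for label {label!r}")
            for r in routes:
                if r.label != label:
                    out.append(f"route under label {label!r} carries label {r.label!r}")
        return out

    def validate(self) -> None:
        problems = self.problems()
        if problems:
            raise ValidationError(problems)

    # -- context overrides (dynamic reconfiguration) -----------------------

    def with_patient_context(self, patient_id: str, context: str) -> "KnowledgeBase":
        """A copy with the patient's context override set (atomic swap)."""
        known = self.contexts()
        if context not in known:
            raise UnknownContextError(
                f"context {context!r} is not a known context key; known: {sorted(known)}"
            )
        overrides = dict(self.patient_contexts)
        overrides[patient_id] = context
        return replace(self, patient_contexts=overrides)


def effective_rules(
    kb: KnowledgeBase,
    patient: PatientProfile | str,
    modality: Modality,
    context: str | None = None,
) -> RuleEntry:
    """Resolve the rule entry governing one patient × modality.

    Resolution order: patient+context > patient > default+context > default.
    The context is, in order of precedence, an administrative override set by
    reconfiguration, the explicit ``context`` argument, or the patient's
    ``location``.
    """
    if isinstance(patient, PatientProfile):
        pid = patient.patient_id
        ctx = kb.patient_contexts.get(pid, context if context is not None else patient.location)
    else:
        pid = patient
        ctx = kb.patient_contexts.get(pid, context)
    for key in (
        (pid, modality, ctx),
        (pid, modality, None),
        (DEFAULT_PATIENT, modality, ctx),
        (DEFAULT_PATIENT, modality, None),
    ):
        entry = kb.entries.get(key)  # type: ignore[arg-type]
        if entry is not None:
            return entry
    raise ConfigurationMissingError(
        f"no rule entry for patient {pid!r}, modality {modality.value!r}"
        + (f", context {ctx!r}" if ctx else "")
    )


# ---------------------------------------------------------------------------
# XML / JSON serialisation
# ---------------------------------------------------------------------------


def _parse_float(text: str | None, what: str, problems: list[str]) -> float | None:
    if text is None:
        problems.append(f"missing attribute: {what}")
        return None
    try:
        return float(text)
    except ValueError:
        problems.append(f"{what} is not a number: {text!r}")
        return None


def _kb_from_etree(root: ET.Element) -> KnowledgeBase:
    problems: list[str] = []
    if root.tag != "knowledgeBase":
        raise ValidationError([f"root element must be <knowledgeBase>, got <{root.tag}>"])
    version = root.get("version", "1")
    author = root.get("author", "")

    entries: dict[Key, RuleEntry] = {}
    for patient_el in root.iterfind("./patients/patient"):
        pid = patient_el.get("id")
        if not pid:
            problems.append("<patient> element without an id attribute")
            continue
        for i, sensor_el in enumerate(patient_el.iterfind("sensor")):
            where = f"patient {pid!r} sensor #{i + 1}"
            mod_text = sensor_el.get("modality")
            try:
                modality = Modality(mod_text)
            except ValueError:
                problems.append(f"{where}: unknown modality {mod_text!r}")
                continue
            context = sensor_el.get("context")  # None → any context
            dvr_el = sensor_el.find("dvr")
            if dvr_el is None:
                problems.append(f"{where}: missing <dvr>")
                continue
            low = _parse_float(dvr_el.get("low"), f"{where} dvr low", problems)
            high = _parse_float(dvr_el.get("high"), f"{where} dvr high", problems)
            if low is None or high is None:
                continue
            rules: list[AnomalyRule] = []
            for rule_el in sensor_el.iterfind("anomaly"):
                side_text = rule_el.get("side")
                label = rule_el.get("label") or ""
                try:
                    side = Side(side_text)
                except ValueError:
                    problems.append(f"{where}: unknown anomaly side {side_text!r}")
                    continue
                if not label:
                    problems.append(f"{where}: anomaly rule without a label")
                    continue
                rules.append(AnomalyRule(side=side, label=label))
            try:
                dvr = DesiredValueRange(low=low, high=high)
                entry = RuleEntry(dvr=dvr, rules=tuple(rules))
            except ValueError as exc:
                problems.append(f"{where}: {exc}")
                continue
            key: Key = (pid, modality, context)
            if key in entries:
                problems.append(
                    f"conflicting entries for (patient={pid!r}, "
                    f"modality={modality.value!r}, context={context!r})"
                )
                continue
            entries[key] = entry

    routes: dict[str, list[NotificationRoute]] = {}
    for j, route_el in enumerate(root.iterfind("./routes/route")):
        where = f"route #{j + 1}"
        label = route_el.get("label") or ""
        provider = route_el.get("provider") or ""
        channel_text = route_el.get("channel")
        address = route_el.get("address") or ""
        if not label or not provider:
            problems.append(f"{where}: label and provider are required")
            continue
        try:
            channel = Channel(channel_text)
        except ValueError:
            problems.append(f"{where}: unknown channel {channel_text!r}")
            continue
        routes.setdefault(label, []).append(
            NotificationRoute(label=label, provider_id=provider, channel=channel, address=address)
        )

    unrouted = frozenset(
        el.get("name") for el in root.iterfind("./unrouted/label") if el.get("name")
    )

    kb = KnowledgeBase(
        entries=entries,
        routes={k: tuple(v) for k, v in routes.items()},
        unrouted=unrouted,
        version=version,
        author=author,
    )
    problems.extend(kb.problems())
    if problems:
        raise ValidationError(problems)
    return kb


def _kb_to_etree(kb: KnowledgeBase) -> ET.Element:
    root = ET.Element("knowledgeBase", version=kb.version)
    if kb.author:
        root.set("author", kb.author)
    patients_el = ET.SubElement(root, "patients")
    by_patient: dict[str, list[tuple[Key, RuleEntry]]] = {}
    for key, entry in kb.entries.items():
        by_patient.setdefault(key[0], []).append((key, entry))
    for pid in sorted(by_patient):
        patient_el = ET.SubElement(patients_el, "patient", id=pid)
        for (pid_, modality, context), entry in sorted(
            by_patient[pid], key=lambda kv: (kv[0][1].value, kv[0][2] or "")
        ):
            attrs = {"modality": modality.value, "unit": _unit_of(modality)}
            if context is not None:
                attrs["context"] = context
            sensor_el = ET.SubElement(patient_el, "sensor", attrs)
            ET.SubElement(sensor_el, "dvr", low=repr(entry.dvr.low), high=repr(entry.dvr.high))
            for rule in sorted(entry.rules, key=lambda r: r.side.value):
                ET.SubElement(sensor_el, "anomaly", side=rule.side.value, label=rule.label)
    routes_el = ET.SubElement(root, "routes")
    for label in sorted(kb.routes):
        for route in kb.routes[label]:
            ET.SubElement(
                routes_el,
                "route",
                label=route.label,
                provider=route.provider_id,
                channel=route.channel.value,
                address=route.address,
            )
    unrouted_el = ET.SubElement(root, "unrouted")
    for label in sorted(kb.unrouted):
        ET.SubElement(unrouted_el, "label", name=label)
    return root


def _unit_of(modality: Modality) -> str:
    from .core import MODALITY_UNITS

    return MODALITY_UNITS[modality]


def _kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "version": kb.version,
        "author": kb.author,
        "patients": [
            {
                "id": pid,
                "modality": modality.value,
                "context": context,
                "dvr": {"low": entry.dvr.low, "high": entry.dvr.high},
                "anomalies": [
                    {"side": r.side.value, "label": r.label}
                    for r in sorted(entry.rules, key=lambda r: r.side.value)
                ],
            }
            for (pid, modality, context), entry in sorted(
                kb.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2] or "")
            )
        ],
        "routes": [
            {
                "label": r.label,
                "provider": r.provider_id,
                "channel": r.channel.value,
                "address": r.address,
            }
            for label in sorted(kb.routes)
            for r in kb.routes[label]
        ],
        "unrouted": sorted(kb.unrouted),
    }


def _kb_from_dict(data: dict) -> KnowledgeBase:
    problems: list[str] = []
    entries: dict[Key, RuleEntry] = {}
    for item in data.get("patients", []):
        try:
            key: Key = (item["id"], Modality(item["modality"]), item.get("context"))
            entry = RuleEntry(
                dvr=DesiredValueRange(low=item["dvr"]["low"], high=item["dvr"]["high"]),
                rules=tuple(
                    AnomalyRule(side=Side(a["side"]), label=a["label"])
                    for a in item["anomalies"]
                ),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"patient entry {item!r}: {exc}")
            continue
        if key in entries:
            problems.append(f"conflicting entries for key {key!r}")
            continue
        entries[key] = entry
    routes: dict[str, list[NotificationRoute]] = {}
    for item in data.get("routes", []):
        try:
            route = NotificationRoute(
                label=item["label"],
                provider_id=item["provider"],
                channel=Channel(item["channel"]),
                address=item.get("address", ""),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"route entry {item!r}: {exc}")
            continue
        routes.setdefault(route.label, []).append(route)
    kb = KnowledgeBase(
        entries=entries,
        routes={k: tuple(v) for k, v in routes.items()},
        unrouted=frozenset(data.get("unrouted", [])),
        version=str(data.get("version", "1")),
        author=data.get("author", ""),
    )
    problems.extend(kb.problems())
    if problems:
        raise ValidationError(problems)
    return kb


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base (XML, or JSON for ``.json`` paths).

    Raises :class:`ValidationError` listing *every* schema violation, or
    :class:`IntegrityError` for unreadable/unparseable files.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return _kb_from_dict(json.loads(text))
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise IntegrityError(f"{path}: not well-formed XML: {exc}") from exc
    return _kb_from_etree(root)


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> Path:
    """Write a validated knowledge base; refuses to persist an invalid one.

    Round-trip guarantee: ``load_knowledge_base(save_knowledge_base(kb, p))``
    equals ``kb`` field-for-field (context overrides excepted — they are
    runtime state, not configuration).
    """
    kb.validate()
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(_kb_to_dict(kb), indent=2) + "\n")
        return path
    root = _kb_to_etree(kb)
    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode") + "\n")
    logger.debug("knowledge base saved to %s (%d entries)", path, len(kb.entries))
    return path
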