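"""XML knowledge base: load, validate, save, and rule resolution."""

import pytest
from hypothesis import given, strategies as st

from vitalagents.core import (
    AnomalyRule,
    Channel,
    DesiredValueRange,
    Modality,
    NotificationRoute,
    Side,
)
from vitalagents.errors import ConfigurationMissingError, ValidationError
from vitalagents.examples import example_knowledge_base
from vitalagents.knowledge_base import (
    DEFAULT_PATIENT,
    KnowledgeBase,
    RuleEntry,
    effective_rules,
    load_knowledge_base,
    save_knowledge_base,
)

EXAMPLE_XML = """
<knowledgeBase version="1">
  <patients>
    <patient id="default">
      <sensor modality="body_temperature" unit="degC">
        <dvr low="36.0" high="36.6"/>
        <anomaly side="below_low" label="Hypothermia"/>
        <anomaly side="above_high" label="Hyperthermia"/>
      </sensor>
      <sensor modality="heart_rate" unit="bpm">
        <dvr low="60" high="110"/>
        <anomaly side="below_low" label="Bradyarrhythmias"/>
        <anomaly side="above_high" label="Tachyarrhythmias"/>
      </sensor>
    </patient>
  </patients>
  <routes>
    <route label="Hypothermia" provider="drA" channel="sms" address="+55000"/>
    <route label="Hyperthermia" provider="drA" channel="sms" address="+55000"/>
    <route label="Bradyarrhythmias" provider="drB" channel="console" address="ward"/>
    <route label="Tachyarrhythmias" provider="drB" channel="console" address="ward"/>
  </routes>
</knowledgeBase>
"""


class TestLoad:
    def test_example_document(self, tmp_path):
        path = tmp_path / "kb.xml"
        path.write_text(EXAMPLE_XML)
        kb = load_knowledge_base(path)
        temp = kb.entries[(DEFAULT_PATIENT, Modality.BODY_TEMPERATURE, None)]
        assert temp.dvr == DesiredValueRange(36.0, 36.6)
        assert temp.rule_for(Side.BELOW_LOW).label == "Hypothermia"
        assert temp.rule_for(Side.ABOVE_HIGH).label == "Hyperthermia"
        hr = kb.entries[(DEFAULT_PATIENT, Modality.HEART_RATE, None)]
        assert (hr.dvr.low, hr.dvr.high) == (60.0, 110.0)
        assert {r.label for r in hr.rules} == {"Bradyarrhythmias", "Tachyarrhythmias"}

    def test_empty_patients_document(self, tmp_path):
        path = tmp_path / "kb.xml"
        path.write_text("<knowledgeBase><patients/><routes/></knowledgeBase>")
        kb = load_knowledge_base(path)
        assert kb.entries == {} and kb.routes == {}

    def test_all_violations_reported_at_once(self, tmp_path):
        bad = """
        <knowledgeBase>
          <patients>
            <patient id="default">
              <sensor modality="body_temperature" unit="degC">
                <dvr low="37.0" high="36.0"/>
                <anomaly side="below_low" label="Hypothermia"/>
                <anomaly side="above_high" label="Hyperthermia"/>
              </sensor>
              <sensor modality="nonsense" unit="x"><dvr low="0" high="1"/></sensor>
              <sensor modality="heart_rate" unit="bpm">
                <dvr low="60" high="abc"/>
                <anomaly side="below_low" label="Bradyarrhythmias"/>
                <anomaly side="above_high" label="Tachyarrhythmias"/>
              </sensor>
            </patient>
          </patients>
          <routes/>
        </knowledgeBase>
        """
        path = tmp_path / "kb.xml"
        path.write_text(bad)
        with pytest.raises(ValidationError) as exc:
            load_knowledge_base(path)
        assert len(exc.value.problems) >= 3

    def test_overlapping_keys_conflict(self, tmp_path):
        dup = """
        <knowledgeBase>
          <patients>
            <patient id="p1">
              <sensor modality="heart_rate" unit="bpm">
                <dvr low="60" high="110"/>
                <anomaly side="below_low" label="A"/>
                <anomaly side="above_high" label="B"/>
              </sensor>
              <sensor modality="heart_rate" unit="bpm">
                <dvr low="50" high="120"/>
                <anomaly side="below_low" label="A"/>
                <anomaly side="above_high" label="B"/>
              </sensor>
            </patient>
          </patients>
          <routes/>
          <unrouted><label name="A"/><label name="B"/></unrouted>
        </knowledgeBase>
        """
        path = tmp_path / "kb.xml"
        path.write_text(dup)
        with pytest.raises(ValidationError, match="conflicting"):
            load_knowledge_base(path)

    def test_unrouted_label_without_marker_rejected(self, tmp_path):
        xml = EXAMPLE_XML.replace(
            '<route label="Hypothermia" provider="drA" channel="sms" address="+55000"/>', ""
        )
        path = tmp_path / "kb.xml"
        path.write_text(xml)
        with pytest.raises(ValidationError, match="Hypothermia"):
            load_knowledge_base(path)


class TestSaveRoundTrip:
    @pytest.mark.parametrize("suffix", ["xml", "json"])
    def test_example_round_trip(self, kb, tmp_path, suffix):
        path = tmp_path / f"kb.{suffix}"
        save_knowledge_base(kb, path)
        assert load_knowledge_base(path) == kb

    def test_refuses_to_save_invalid_kb(self, tmp_path):
        kb = example_knowledge_base(routes=False)
        kb = KnowledgeBase(entries=kb.entries, routes={}, unrouted=frozenset())
        with pytest.raises(ValidationError):
            save_knowledge_base(kb, tmp_path / "kb.xml")


# -- property-based round trip ------------------------------------------------

_label = st.text(alphabet="abcdefghijklmnopqrstuvwxyzABC0123456789_", min_size=1, max_size=12)
_context = st.sampled_from([None, "ward", "icu", "home"])


@st.composite
def knowledge_bases(draw):
    n = draw(st.integers(min_value=0, max_value=50))
    entries = {}
    labels = set()
    for _ in range(n):
        key = (
            draw(st.sampled_from(["default", "p1", "p2", "p3", "p4"])),
            draw(st.sampled_from(list(Modality))),
            draw(_context),
        )
        if key in entries:
            continue
        low = draw(st.floats(min_value=-1000, max_value=1000, allow_nan=False, width=32))
        span = draw(st.floats(min_value=0, max_value=500, allow_nan=False, width=32))
        lo_label = draw(_label)
        hi_label = draw(_label.filter(lambda s: s != lo_label))
        entries[key] = RuleEntry(
            dvr=DesiredValueRange(low=float(low), high=float(low) + float(span)),
            rules=(
                AnomalyRule(side=Side.BELOW_LOW, label=lo_label),
                AnomalyRule(side=Side.ABOVE_HIGH, label=hi_label),
            ),
        )
        labels.update({lo_label, hi_label})
    routes = {}
    unrouted = set()
    for label in sorted(labels):
        if draw(st.booleans()):
            routes[label] = (
                NotificationRoute(
                    label=label,
                    provider_id=draw(st.sampled_from(["drA", "drB"])),
                    channel=draw(st.sampled_from(list(Channel))),
                    address=draw(_label),
                ),
            )
        else:
            unrouted.add(label)
    return KnowledgeBase(entries=entries, routes=routes, unrouted=frozenset(unrouted))


@given(kb=knowledge_bases(), suffix=st.sampled_from(["xml", "json"]))
def test_generated_kb_round_trip(kb, suffix, tmp_path_factory):
    path = tmp_path_factory.mktemp("kb") / f"kb.{suffix}"
    save_knowledge_base(kb, path)
    assert load_knowledge_base(path) == kb


# -- effective_rules ----------------------------------------------------------

class TestEffectiveRules:
    def _kb_with_override(self):
        kb = example_knowledge_base()
        entries = dict(kb.entries)
        entries[("p1", Modality.BODY_TEMPERATURE, None)] = RuleEntry(
            dvr=DesiredValueRange(36.0, 37.0),
            rules=(
                AnomalyRule(side=Side.BELOW_LOW, label="Hypothermia"),
                AnomalyRule(side=Side.ABOVE_HIGH, label="Hyperthermia"),
            ),
        )
        entries[(DEFAULT_PATIENT, Modality.BODY_TEMPERATURE, "icu")] = RuleEntry(
            dvr=DesiredValueRange(36.2, 36.4),
            rules=(
                AnomalyRule(side=Side.BELOW_LOW, label="Hypothermia"),
                AnomalyRule(side=Side.ABOVE_HIGH, label="Hyperthermia"),
            ),
        )
        return KnowledgeBase(entries=entries, routes=kb.routes, unrouted=kb.unrouted)

    def test_patient_override_wins_over_default(self):
        kb = self._kb_with_override()
        entry = effective_rules(kb, "p1", Modality.BODY_TEMPERATURE)
        assert entry.dvr.high == 37.0

    def test_default_applies_without_override(self, kb):
        entry = effective_rules(kb, "p9", Modality.BODY_TEMPERATURE)
        assert entry.dvr == DesiredValueRange(36.0, 36.6)

    def test_context_specific_default_beats_plain_default_for_other_patient(self):
        kb = self._kb_with_override()
        entry = effective_rules(kb, "p2", Modality.BODY_TEMPERATURE, context="icu")
        assert (entry.dvr.low, entry.dvr.high) == (36.2, 36.4)

    def test_unconfigured_modality_raises(self, kb):
        with pytest.raises(ConfigurationMissingError, match="spo2"):
            effective_rules(kb, "p1", Modality.SPO2)

    def test_total_over_patients_and_configured_modalities(self, kb):
        for pid in ["p1", "p2", "anyone"]:
            for modality in [Modality.HEART_RATE, Modality.BODY_TEMPERATURE]:
                assert effective_rules(kb, pid, modality) is not None
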