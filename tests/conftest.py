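import pytest
from hypothesis import settings

from vitalagents.core import PatientProfile, Sex
from vitalagents.examples import example_knowledge_base
from vitalagents.storage import InMemoryStore, PatientRegistry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_registry(patient_ids=("p1",), location=""):
    registry = PatientRegistry()
    for i, pid in enumerate(patient_ids):
        registry.add(
            PatientProfile(
                patient_id=pid,
                rfid_tag=f"{i:08x}",
                name=pid,
                age=60,
                sex=Sex.OTHER,
                location=location,
            )
        )
    return registry


@pytest.fixture
def kb():
    return example_knowledge_base()


@pytest.fixture
def registry():
    return make_registry()


def run_scenario(scenario, kb, registry=None, config=None):
    """Generate a scenario, feed it through a full monitoring session."""
    from vitalagents.pipeline import MonitoringSession, PipelineConfig
    from vitalagents.stream import generate

    if registry is None:
        registry = make_registry(tuple(scenario.patients))
    readings, truth = generate(scenario, kb, registry)
    store = InMemoryStore()
    for reading in readings:
        store.append(reading)
    session = MonitoringSession(kb, store, registry, config or PipelineConfig())
    result = session.run(scenario.duration + session.config.ticker_period)
    return readings, truth, result
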