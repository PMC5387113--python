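"""Synthetic stream generator: determinism, ground truth, confusion tallies."""

import pytest

from vitalagents.core import Activity, Modality, SignalQuality
from vitalagents.errors import ScenarioError
from vitalagents.rules import Status
from vitalagents.stream import (
    ActivityEpisode,
    BaselineSpec,
    InjectedAnomaly,
    QualityDropout,
    StreamScenario,
    generate,
    ground_truth_compare,
    load_scenario,
)

from conftest import run_scenario


class TestGenerate:
    def test_single_temperature_anomaly_ground_truth(self, kb):
        scenario = StreamScenario(
            seed=3,
            duration=60,
            anomalies=[
                InjectedAnomaly(time=20, modality=Modality.BODY_TEMPERATURE, value=37.8)
            ],
        )
        readings, truth = generate(scenario, kb)
        assert [t.label for t in truth] == ["Hyperthermia"]
        injected = [r for r in readings if r.value == 37.8]
        assert len(injected) == 1

    def test_zero_anomaly_scenario_detects_nothing(self, kb):
        scenario = StreamScenario(seed=4, duration=120)
        _, truth, result = run_scenario(scenario, kb)
        assert truth == [] and result.events == []

    def test_deterministic_for_fixed_seed(self, kb):
        scenario = StreamScenario(
            seed=11,
            duration=400,
            anomalies=[
                InjectedAnomaly(time=4 * i, modality=Modality.HEART_RATE, value=130.0)
                for i in range(0, 100, 2)
            ] + [
                InjectedAnomaly(time=4 * i + 2, modality=Modality.BODY_TEMPERATURE, value=37.8)
                for i in range(0, 100, 2)
            ],
        )
        r1, t1 = generate(scenario, kb)
        r2, t2 = generate(scenario, kb)
        assert r1 == r2 and t1 == t2 and len(t1) == 100

    def test_baseline_values_stay_inside_dvr(self, kb):
        scenario = StreamScenario(seed=5, duration=300)
        readings, _ = generate(scenario, kb)
        for r in readings:
            if r.modality is Modality.BODY_TEMPERATURE:
                assert 36.0 <= r.value <= 36.6
            else:
                assert 60.0 <= r.value <= 110.0

    @pytest.mark.parametrize("seed", range(20))
    def test_baseline_only_streams_are_alert_free(self, kb, seed):
        scenario = StreamScenario(seed=seed, duration=100)
        _, _, result = run_scenario(scenario, kb)
        assert result.events == [] and result.records == []

    def test_injected_value_inside_dvr_rejected(self, kb):
        scenario = StreamScenario(
            seed=1,
            duration=60,
            anomalies=[InjectedAnomaly(time=10, modality=Modality.BODY_TEMPERATURE, value=36.3)],
        )
        with pytest.raises(ScenarioError, match="inside the DVR"):
            generate(scenario, kb)

    def test_expected_label_contradiction_rejected(self, kb):
        scenario = StreamScenario(
            seed=1,
            duration=60,
            anomalies=[
                InjectedAnomaly(
                    time=10,
                    modality=Modality.BODY_TEMPERATURE,
                    value=37.8,
                    expected_label="Hypothermia",
                )
            ],
        )
        with pytest.raises(ScenarioError, match="forces"):
            generate(scenario, kb)

    def test_quality_and_activity_windows_annotate_readings(self, kb):
        scenario = StreamScenario(
            seed=1,
            duration=40,
            dropouts=[QualityDropout(start=10, end=20)],
            activity_episodes=[ActivityEpisode(start=30, end=40)],
        )
        readings, _ = generate(scenario, kb)
        for r in readings:
            t = (r.timestamp.dt - readings[0].timestamp.dt).total_seconds()
            if 10 <= t < 20:
                assert r.signal_quality is SignalQuality.POOR
            if 30 <= t < 40:
                assert r.activity is Activity.ACTIVE


class TestGroundTruthCompare:
    def test_perfect_conditions_full_recall_and_precision(self, kb):
        scenario = StreamScenario(
            seed=6,
            duration=200,
            anomalies=[
                InjectedAnomaly(time=20 * i, modality=Modality.HEART_RATE, value=55.0)
                for i in range(1, 6)
            ],
        )
        _, truth, result = run_scenario(scenario, kb)
        counts = ground_truth_compare(result.events, truth, tolerance=2,
                                      suppressed=result.suppressed)
        assert (counts.tp, counts.fp, counts.fn) == (5, 0, 0)
        assert counts.recall == 1.0 and counts.precision == 1.0

    def test_anomaly_in_dropout_counts_as_fn_and_quality_tally(self, kb):
        scenario = StreamScenario(
            seed=7,
            duration=60,
            anomalies=[InjectedAnomaly(time=10, modality=Modality.BODY_TEMPERATURE, value=37.8)],
            dropouts=[QualityDropout(start=8, end=14)],
        )
        _, truth, result = run_scenario(scenario, kb)
        counts = ground_truth_compare(result.events, truth, tolerance=2,
                                      suppressed=result.suppressed)
        assert counts.tp == 0 and counts.fp == 0
        assert counts.fn == 1 and counts.suppressed_quality == 1

    def test_activity_covered_anomaly_goes_to_context_tally(self, kb):
        # 130 bpm during activity sits inside the widened 60-150 range
        scenario = StreamScenario(
            seed=8,
            duration=60,
            anomalies=[InjectedAnomaly(time=10, modality=Modality.HEART_RATE, value=130.0)],
            activity_episodes=[ActivityEpisode(start=8, end=14)],
        )
        _, truth, result = run_scenario(scenario, kb)
        counts = ground_truth_compare(result.events, truth, tolerance=2,
                                      suppressed=result.suppressed)
        assert counts.suppressed_context == 1
        assert counts.tp == 0 and counts.fp == 0 and counts.fn == 0

    def test_hand_computed_tallies_small_scenario(self, kb):
        """10-sample scenario with one clean, one gated, one excused anomaly."""
        scenario = StreamScenario(
            seed=9,
            duration=20,
            baselines={
                Modality.HEART_RATE: BaselineSpec(mean=72.0, sd=6.0, sample_period=2)
            },
            anomalies=[
                InjectedAnomaly(time=2, modality=Modality.HEART_RATE, value=55.0),
                InjectedAnomaly(time=8, modality=Modality.HEART_RATE, value=120.0),
                InjectedAnomaly(time=14, modality=Modality.HEART_RATE, value=130.0),
            ],
            dropouts=[QualityDropout(start=8, end=10)],
            activity_episodes=[ActivityEpisode(start=14, end=16)],
        )
        _, truth, result = run_scenario(scenario, kb)
        counts = ground_truth_compare(result.events, truth, tolerance=2,
                                      suppressed=result.suppressed)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 1)
        assert counts.suppressed_quality == 1
        assert counts.suppressed_context == 1


class TestScenarioFiles:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "seed: 42\n"
            "duration: 60\n"
            "anomalies:\n"
            "  - {time: 10, modality: body_temperature, value: 37.8}\n"
        )
        scenario = load_scenario(path)
        assert scenario.seed == 42
        assert scenario.anomalies[0].value == 37.8

    def test_interval_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            StreamScenario(seed=0, duration=10, dropouts=[QualityDropout(start=5, end=20)])
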