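"""Synthetic vital-sign streams with ground truth.

Stands in for the sensing hardware (pulse and temperature sensors wired to
an internet-enabled microcontroller): generates deterministic, seeded
streams of readings with explicitly injected anomalies, signal-quality
dropouts and activity episodes, so the whole pipeline is testable without
hardware.

Baseline values are drawn from a Gaussian truncated to the effective DVR,
so a baseline-only stream can never trigger an alert and every injected
anomaly's label is forced by the rule set — the ground truth is exact by
construction, not statistical.

Scenarios are plain data (YAML or JSON files, or constructed in code); the
seed is recorded in every export header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .core import (
    Activity,
    AnomalyEvent,
    DEFAULT_EPOCH,
    Instant,
    Modality,
    Reading,
    SignalQuality,
)
from .errors import ScenarioError
from .knowledge_base import KnowledgeBase, effective_rules
from .rules import Status, classify
from .storage import PatientRegistry

__all__ = [
    "BaselineSpec",
    "InjectedAnomaly",
    "QualityDropout",
    "ActivityEpisode",
    "StreamScenario",
    "TruthEntry",
    "generate",
    "ConfusionCounts",
    "ground_truth_compare",
    "load_scenario",
]


class BaselineSpec(BaseModel):
    """Per-modality baseline signal: mean, spread, sampling period."""

    mean: float
    sd: float = Field(gt=0)
    sample_period: int = Field(gt=0)


class InjectedAnomaly(BaseModel):
    """One anomaly injected as an explicit value at a given stream time.

    The value must lie strictly outside the effective DVR so its label is
    forced by the rule set; ``expected_label``, when given, is checked
    against that forced label at validation time.
    """

    time: int = Field(ge=0)
    patient_id: str = "p1"
    modality: Modality
    value: float
    expected_label: str | None = None


class QualityDropout(BaseModel):
    """Half-open interval [start, end) during which signal quality degrades."""

    start: int = Field(ge=0)
    end: int
    quality: SignalQuality = SignalQuality.POOR

    @model_validator(mode="after")
    def _ordered(self):
        if self.end <= self.start:
            raise ValueError("dropout end must exceed start")
        return self


class ActivityEpisode(BaseModel):
    """Half-open interval [start, end) of patient activity context."""

    start: int = Field(ge=0)
    end: int
    activity: Activity = Activity.ACTIVE

    @model_validator(mode="after")
    def _ordered(self):
        if self.end <= self.start:
            raise ValueError("episode end must exceed start")
        return self


class StreamScenario(BaseModel):
    """Full description of one synthetic monitoring run."""

    seed: int = 0
    duration: int = Field(gt=0)
    patients: list[str] = Field(default_factory=lambda: ["p1"])
    baselines: dict[Modality, BaselineSpec] = Field(
        default_factory=lambda: {
            Modality.HEART_RATE: BaselineSpec(mean=72.0, sd=6.0, sample_period=2),
            Modality.BODY_TEMPERATURE: BaselineSpec(mean=36.3, sd=0.12, sample_period=2),
        }
    )
    anomalies: list[InjectedAnomaly] = Field(default_factory=list)
    dropouts: list[QualityDropout] = Field(default_factory=list)
    activity_episodes: list[ActivityEpisode] = Field(default_factory=list)

    @model_validator(mode="after")
    def _within_duration(self):
        for window in [*self.dropouts, *self.activity_episodes]:
            if window.end > self.duration:
                raise ValueError("dropout/activity interval exceeds scenario duration")
        for anomaly in self.anomalies:
            if anomaly.time >= self.duration:
                raise ValueError("injected anomaly time beyond scenario duration")
        return self


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one injected anomaly (time snapped to sample grid)."""

    time: int
    patient_id: str
    modality: Modality
    label: str
    value: float


def _quality_at(t: int, dropouts: list[QualityDropout]) -> SignalQuality:
    for d in dropouts:
        if d.start <= t < d.end:
            return d.quality
    return SignalQuality.GOOD


def _activity_at(t: int, episodes: list[ActivityEpisode]) -> Activity:
    for e in episodes:
        if e.start <= t < e.end:
            return e.activity
    return Activity.REST


def generate(
    scenario: StreamScenario,
    kb: KnowledgeBase,
    registry: PatientRegistry | None = None,
    epoch=DEFAULT_EPOCH,
) -> tuple[list[Reading], list[TruthEntry]]:
    """Generate the readings and ground-truth track of a scenario.

    Deterministic for a fixed seed.  Raises :class:`ScenarioError` when an
    injected value falls inside the DVR (it would corrupt the ground
    truth) or contradicts its declared expected label.
    """
    rng = np.random.default_rng(scenario.seed)
    readings: list[tuple[int, Reading]] = []
    truth: list[TruthEntry] = []

    for pid in scenario.patients:
        patient = registry.patients[pid] if registry is not None else pid
        for modality, spec in scenario.baselines.items():
            entry = effective_rules(kb, patient, modality)
            dvr = entry.dvr
            times = np.arange(0, scenario.duration, spec.sample_period, dtype=int)
            a = (dvr.low - spec.mean) / spec.sd
            b = (dvr.high - spec.mean) / spec.sd
            values = stats.truncnorm.rvs(
                a, b, loc=spec.mean, scale=spec.sd, size=len(times), random_state=rng
            )
            # map injected anomalies onto the sample grid for this stream
            injected: dict[int, InjectedAnomaly] = {}
            for anomaly in scenario.anomalies:
                if anomaly.patient_id != pid or anomaly.modality is not modality:
                    continue
                slot = int(anomaly.time // spec.sample_period)
                if slot >= len(times):
                    raise ScenarioError(f"anomaly at t={anomaly.time} beyond stream end")
                if slot in injected:
                    raise ScenarioError(
                        f"two anomalies map to the same {modality.value} sample at "
                        f"t={int(times[slot])} (sample period {spec.sample_period}s)"
                    )
                if dvr.contains(anomaly.value):
                    raise ScenarioError(
                        f"injected {modality.value} value {anomaly.value} lies inside the "
                        f"DVR [{dvr.low}, {dvr.high}] — ground truth would be corrupted"
                    )
                injected[slot] = anomaly

            sensor_id = f"{pid}-{modality.value}"
            for i, t in enumerate(times):
                t = int(t)
                value = float(values[i])
                if i in injected:
                    anomaly = injected[i]
                    value = anomaly.value
                    probe = Reading(
                        patient_id=pid,
                        sensor_id=sensor_id,
                        modality=modality,
                        timestamp=_instant(epoch, t),
                        value=value,
                    )
                    forced = classify(probe, dvr, entry.rules)
                    assert forced.status is Status.ANOMALOUS  # guaranteed by the DVR check
                    if anomaly.expected_label is not None and anomaly.expected_label != forced.label:
                        raise ScenarioError(
                            f"anomaly at t={anomaly.time}: expected label "
                            f"{anomaly.expected_label!r} but the rule set forces {forced.label!r}"
                        )
                    truth.append(
                        TruthEntry(
                            time=t, patient_id=pid, modality=modality,
                            label=forced.label, value=value,
                        )
                    )
                readings.append(
                    (
                        t,
                        Reading(
                            patient_id=pid,
                            sensor_id=sensor_id,
                            modality=modality,
                            timestamp=_instant(epoch, t),
                            value=value,
                            signal_quality=_quality_at(t, scenario.dropouts),
                            activity=_activity_at(t, scenario.activity_episodes),
                        ),
                    )
                )

    readings.sort(key=lambda tr: (tr[0], tr[1].patient_id, tr[1].sensor_id))
    truth.sort(key=lambda e: (e.time, e.patient_id, e.modality.value))
    return [r for _, r in readings], truth


def _instant(epoch, t: int) -> Instant:
    from datetime import timedelta

    return Instant(epoch + timedelta(seconds=int(t)))


# ---------------------------------------------------------------------------
# Ground-truth comparison
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Detection outcome tallies against the injected ground truth.

    ``suppressed_quality`` and ``suppressed_context`` count injected
    anomalies excused by the false-alarm strategies; quality suppressions
    additionally count as false negatives (the anomaly was real and
    missed), while context suppressions do not (the widened range
    legitimately covers them).
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    suppressed_quality: int = 0
    suppressed_context: int = 0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")


def ground_truth_compare(
    events: list[AnomalyEvent],
    truth: list[TruthEntry],
    *,
    tolerance: int,
    epoch=DEFAULT_EPOCH,
    suppressed=(),
) -> ConfusionCounts:
    """Match detected events against the truth track.

    A detection matches a truth entry when patient, modality and label
    agree and the reading time is within ``tolerance`` seconds (one sample
    period) of the injection time.  ``suppressed`` takes the pipeline's
    suppressed-reading log so gated injections are tallied separately.
    """
    counts = ConfusionCounts()
    unmatched = list(truth)

    def _find(pid: str, modality: Modality, t: int, label: str | None) -> TruthEntry | None:
        for entry in unmatched:
            if entry.patient_id != pid or entry.modality is not modality:
                continue
            if label is not None and entry.label != label:
                continue
            if abs(entry.time - t) <= tolerance:
                return entry
        return None

    for event in events:
        r = event.reading
        t = int((r.timestamp.dt - epoch).total_seconds())
        match = _find(r.patient_id, r.modality, t, event.label)
        if match is not None:
            unmatched.remove(match)
            counts.tp += 1
        else:
            counts.fp += 1

    for item in suppressed:
        r = item.reading
        t = int((r.timestamp.dt - epoch).total_seconds())
        match = _find(r.patient_id, r.modality, t, None)
        if match is None:
            continue
        unmatched.remove(match)
        if item.classification.status is Status.SUPPRESSED_QUALITY:
            counts.suppressed_quality += 1
            counts.fn += 1
        else:
            counts.suppressed_context += 1

    counts.fn += len(unmatched)
    return counts


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------


def load_scenario(path) -> StreamScenario:
    """Load a scenario from YAML or JSON (YAML is a JSON superset here)."""
    from pathlib import Path

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return StreamScenario.model_validate(data)
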