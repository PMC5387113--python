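# vitalagents

A multi-agent remote-patient-monitoring (RPM) simulator and library.
It is written for health-informatics researchers and engineers who need a
self-contained, deterministic testbed for rule-based clinical alerting:
vital-sign streams are classified against per-patient thresholds,
anomalies are routed to health providers over pluggable notification
channels, and every step of the alerting workflow is timestamped so its
latency can be measured.

## The model

Each patient × sensor pair carries a **desired value range (DVR)**
`[low, high]` — e.g. 36.0–36.6 °C for body temperature, 60–110 bpm for
heart rate. A reading with value `v` is normal iff `low ≤ v ≤ high`
(bounds inclusive); the strict complement is covered by two labelled
**anomaly rules** (`v < low` → e.g. *Hypothermia* or *Bradyarrhythmias*;
`v > high` → *Hyperthermia* or *Tachyarrhythmias*). Two false-alarm
strategies precede classification: a **signal-quality gate** that ignores
readings whose sensor reports unreliable contact, and **context
adjustment** that widens the heart-rate DVR (default +40 bpm) while the
patient is physically active.

Monitoring is performed by software agents on a deterministic
discrete-event scheduler: a *monitoring agent* (cyclic ticker behavior)
retrieves new readings each period and classifies them; a *notification
agent* (one-shot behavior) dispatches each anomaly over its configured
routes. Five timestamps bracket the workflow — retrieval (T1), detection
(T2), routine start (T3), send (T4), receipt (T5, minute resolution) —
and four intervals summarise responsiveness:

```
DAI = T2 − T1    detection anomaly interval
NSI = T3 − T2    notification start interval
NP  = T4 − T3    notification period
NRI = T5 − T4    notification routine interval (a bound: T5 is coarse)
```

All clocks are simulated at 1-second resolution, so a run is a pure
function of (configuration, scenario, seed).

## Worked example

```sh
# write the example knowledge base (XML) and a scenario
python - <<'EOF'
from vitalagents.examples import example_knowledge_base
from vitalagents.knowledge_base import save_knowledge_base
save_knowledge_base(example_knowledge_base(), "kb.xml")
open("scenario.yaml", "w").write("""seed: 7
duration: 120
anomalies:
  - {time: 20, modality: body_temperature, value: 37.8}
  - {time: 50, modality: heart_rate, value: 55}
  - {time: 90, modality: heart_rate, value: 130}
""")
EOF

vitalagents simulate --kb kb.xml --scenario scenario.yaml --out out
```

prints

```
3 anomalies, 3 notifications; delay means {'rows': 3, 'mean_dai': 3.0, 'mean_nsi': 0.0, 'mean_np': 2.0}
```

and writes `out/notifications.csv` in the telemetry layout:

```
T1,T2,T3,T4,T5,DAI,NSI,NP
2016-11-04-173424,2016-11-04-173427,2016-11-04-173427,2016-11-04-173429,2016-11-04-1735,3,0,2
2016-11-04-173454,2016-11-04-173457,2016-11-04-173457,2016-11-04-173459,2016-11-04-1735,3,0,2
2016-11-04-173530,2016-11-04-173533,2016-11-04-173533,2016-11-04-173535,2016-11-04-1736,3,0,2
```

Three injected anomalies (a 37.8 °C fever, a 55 bpm bradycardia, a
130 bpm tachycardia) were each detected within one monitoring tick
(DAI = 3 s: 2 s retrieval + 1 s classification), handed to the
notification agent in the same tick (NSI = 0), and sent over the
simulated-SMS channel in 2 s (NP). T5 is recorded only to the minute, as
phones report SMS receipt, so NRI is a bound rather than a point value.
`vitalagents report-delays out/notifications.csv` re-parses the CSV,
recomputes every interval from the timestamps and cross-checks the stated
columns (`"mismatches": 0`); `--streams out/streams.csv --plot p.png`
adds a line chart per sensor stream.

## Layout

| module | role |
|---|---|
| `vitalagents.core` | domain types, timestamp dialect, interval arithmetic |
| `vitalagents.knowledge_base` | XML/JSON rule + route configuration, resolution order |
| `vitalagents.rules` | classification, quality gate, context adjustment, reconfiguration |
| `vitalagents.runtime` | deterministic ticker/one-shot agent scheduler and message bus |
| `vitalagents.pipeline` | monitoring/notification agents, channel stubs, delay telemetry |
| `vitalagents.storage` | pluggable reading stores, RFID patient registry, CSV/JSON-lines |
| `vitalagents.stream` | seeded synthetic vital-sign generator with ground truth |
| `vitalagents.cli` | `vitalagents validate | simulate | report-delays` |

See `docs/methods.md` for the model's assumptions, defaults and
limitations.
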