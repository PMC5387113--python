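# Methods

## Monitoring model

The simulator models threshold-based clinical alerting. For every
patient × sensor modality an effective rule entry is resolved from the
knowledge base with specificity order **patient+context > patient >
default+context > default**, where a *context* is a ward/room key (a
patient's context can be changed at runtime by an administrator;
resolution is atomic because reconfiguration returns a fresh knowledge
base that callers swap at a batch boundary).

Classification is a trichotomy on the desired value range (DVR): a value
exactly at a bound is **normal** (a 36.0–36.6 °C range flags 36.7, not
36.6; the anomaly rules are the strict complement `v < low` / `v > high`).
This inclusive-bound convention is a design choice made once; the
alternative (exclusive bounds) would reclassify only measure-zero inputs
but would break the "range means acceptable values" reading of the
configuration format.

Two suppression stages run before classification, in fixed order:

1. **Signal-quality gate.** Readings whose sensor self-reports `poor` or
   `missing` quality are never classified — quality wins over any
   anomaly, because an unreliable electrode says nothing about the
   patient. The gate can be disabled per run. Suppressed readings are
   retained and marked, not dropped, for audit and for the batch oracle
   used in testing.
2. **Context adjustment.** During activity episodes the heart-rate DVR
   high bound is widened additively, +40 bpm by default. The widening is
   a configuration table per modality, not code; no published number
   exists for it, so the default was chosen as a conservative exercise
   allowance (a resting band of 60–110 bpm extended to 150 bpm covers
   moderate exertion without masking ventricular rates). A value
   anomalous under the raw DVR but normal under the widened one is
   reported as *context-suppressed*, distinct from plain normal.
   We chose DVR widening over a post-detection grace period because it
   keeps the detector stateless per reading.

## Agent scheduling

Agents run on a single-threaded discrete-event loop over a simulated
clock at 1-second resolution; concurrency is modeled, not real. A
**ticker** behavior with period `p` registered at `t0` fires at
`t0, t0+p, …` (first firing immediately; a flag restores the
wait-one-period convention). `run_until(t_end)` therefore executes
`⌊(t_end−t0)/p⌋+1` firings. Simultaneous events are ordered by (agent
registration order, behavior index, sequence number) — the tie-break is
part of the contract, so identical inputs yield byte-identical event
logs. Messages are delivered exactly once, FIFO per sender–receiver
pair, after a configurable delivery latency (default 0 s: same-tick
handoff); messages to unknown receivers go to a dead-letter log, never
silently vanish.

## Latency semantics and defaults

| parameter | default | meaning |
|---|---|---|
| `ticker_period` | 6 s | monitoring cycle length |
| `retrieval_latency` | 2 s | fetching the new-readings batch (T1 → start of analysis) |
| `classify_latency` | 1 s | analysing the batch (→ T2) |
| `delivery_latency` | 0 s | message bus handoff (T2 → T3), hence NSI = 0 |
| SMS `send_latency` | 2 s | notification routine duration (T3 → T4) |
| SMS `receipt_latency` | 45 s | transit to the provider's phone (T4 → T5) |

T1 is stamped once per tick (batch retrieval); every anomaly in the
batch shares T2 = T1 + retrieval + classification latency, so
DAI = 3 s under the defaults — the order of magnitude a small
cloud-polling deployment exhibits. The configuration validator requires
retrieval + classification to fit within one ticker period (an analysis
that outlasted its tick would fall behind the stream); this makes the
latency bound `DAI ≤ p + sample_period` structural. T5 is stored at
minute resolution, emulating SMS receipts, so NRI is reported as a
`[max(0, T5−T4), T5+59−T4]` bound pair rather than a point value.

The bundled six-row example telemetry trace averages DAI 3.33 s and
NP 1.67 s over its printed rows; the tests and the acceptance script
recompute these row-level means from the timestamps. Headline averages
quoted elsewhere for such systems may aggregate over additional
unprinted runs and are deliberately not targeted.

## Synthetic streams and what they show

The generator stands in for the sensing hardware. Baselines are drawn
from a Gaussian **truncated to the effective DVR** (via
`scipy.stats.truncnorm`), so a baseline-only stream can never alarm and
every injected anomaly — an explicit out-of-range value snapped to the
sample grid — has a label forced by the rule set. Ground truth is
therefore exact by construction, and the expected detection performance
on clean scenarios is recall = precision = 100%: the detector is exact,
not statistical. Default baselines: heart rate mean 72 bpm, sd 6 bpm;
temperature mean 36.3 °C, sd 0.12 °C; both sampled every 2 s.

What passing tests do **not** show about real data: the generator has no
waveform morphology, drift, autocorrelation, missingness patterns or
sensor calibration error, so perfect recall here says nothing about
threshold adequacy on physiological signals — only that the pipeline
machinery (gating, adjustment, classification, scheduling, routing,
telemetry) is correct.

## Storage

Back-ends implement a small contract (append, range query, high-water
mark) and register by name — the concrete rendering of the framework's
hot-spot pattern. Ranges are half-open `[from, to)`; readings are
immutable and deduplicated on (patient, sensor, timestamp, value). The
cached-storage strategy is a buffer-and-flush wrapper: appends during an
outage queue locally and replay in order on recovery. The in-memory and
JSON-lines back-ends pass the same conformance suite.

## Numerical and procedural choices

- Timestamps: integer seconds on a simulated clock; text dialect
  `YYYY-MM-DD-HHMMSS` / `YYYY-MM-DD-HHMM` (coarse); no time zones or
  sub-second resolution. Interval arithmetic is exact integer
  subtraction; non-monotone timestamps raise an ordering error naming
  the offending record/line.
- Knowledge-base validation is eager and exhaustive: every problem in a
  document is reported, and every anomaly label must either have a
  route or be explicitly listed as unrouted.
- Unrouted anomalies at runtime are parked in an explicit queue and
  logged as an alerting gap — a monitoring system must not crash on a
  configuration hole.
- Channel failures are retried (default 3 attempts) before a failure
  record is emitted.
- Problem sizes in the test suite: the streaming-vs-batch equivalence
  check runs 100 randomized scenarios, mostly 60–600 s with two streams
  sampled at 2 s, plus two ~10⁴-reading instances; the latency-bound
  check runs 50 seeded scenarios with periods 3–12 s.

## Known limitations

- No trend, multivariate, or learned anomaly detection; thresholds only.
- Notification channels are latency stubs; no real SMS/email/voice
  delivery, escalation or acknowledgment workflows.
- Remote/cloud storage is an extension point, not an implementation.
- NRI depends on receipt hardware in a real deployment; here it is a
  configured latency reported as a minute-resolution bound.
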