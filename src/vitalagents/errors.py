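"""Exception hierarchy shared by all vitalagents modules."""

from __future__ import annotations


class VitalAgentsError(Exception):
    """Base class for every error raised by this package."""


class TimestampFormatError(VitalAgentsError):
    """A timestamp string does not match the telemetry dialect."""


class OrderingError(VitalAgentsError):
    """Timestamps are out of order — a sign of corrupted telemetry."""


class ValidationError(VitalAgentsError):
    """Eager, exhaustive validation failure.

    Carries *every* problem found, not just the first, so configuration
    mistakes surface all at once before monitoring starts.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConfigurationMissingError(VitalAgentsError):
    """No rule entry resolves for a (patient, modality) pair."""


class IntegrityError(VitalAgentsError):
    """A uniqueness invariant is violated (duplicate id, tag, or key)."""


class UnknownContextError(VitalAgentsError):
    """A reconfiguration names a context key absent from the knowledge base."""


class ScenarioError(VitalAgentsError):
    """A synthetic-stream scenario would corrupt its own ground truth."""


class StoreUnavailableError(VitalAgentsError):
    """The reading store's back-end cannot be reached."""


class ChannelError(VitalAgentsError):
    """A notification channel adapter failed to send."""
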