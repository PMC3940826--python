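"""Exception hierarchy for input validation and pipeline failures."""

from __future__ import annotations


class GlycodiaryError(Exception):
    """Base class for all package errors."""


class SchemaError(GlycodiaryError):
    """An input table is missing required columns or has unparseable values."""


class PairingError(GlycodiaryError):
    """Matched-pair structure violated (e.g. two same-arm members in a pair)."""

    def __init__(self, message: str, pair_ids: list[str] | None = None):
        super().__init__(message)
        self.pair_ids = pair_ids or []


class CoverageError(GlycodiaryError):
    """A participant's diary does not cover the required recording days."""

    def __init__(self, message: str, participant_ids: list[str] | None = None):
        super().__init__(message)
        self.participant_ids = participant_ids or []


class WeekendRuleError(GlycodiaryError):
    """A participant's diary has no recorded weekend day."""

    def __init__(self, message: str, participant_ids: list[str] | None = None):
        super().__init__(message)
        self.participant_ids = participant_ids or []


class UnresolvedCodeError(GlycodiaryError):
    """Diary food codes missing from the composition table; aborts the run."""

    def __init__(self, message: str, codes: list[str] | None = None):
        super().__init__(message)
        self.codes = codes or []


class CompositionError(GlycodiaryError):
    """A composition record violates a nutrient invariant (e.g. negative carbohydrate)."""


class DegenerateDataError(GlycodiaryError):
    """A statistical routine received data it cannot test (zero variance, no pairs)."""


class ConfigError(GlycodiaryError):
    """Invalid run or generator configuration."""
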