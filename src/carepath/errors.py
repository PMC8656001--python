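"""Exception hierarchy."""

from __future__ import annotations


class CarepathError(Exception):
    """Base class for all package errors."""


class CdmSchemaError(CarepathError):
    """Table header does not match the preset header of the data model."""


class CdmRowError(CarepathError):
    """A data row could not be parsed into a typed record."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class CdmDialectError(CarepathError):
    """A field value is illegal under the unquoted CSV dialect."""


class CdmEncodingError(CarepathError):
    """File is not valid UTF-8."""


class TimestampFormatError(CarepathError):
    """Timestamp text is not ISO-8601 date or date-time."""


class UnmappedValueError(CarepathError):
    """A raw coded value has no entry in the normalized dictionary."""

    def __init__(self, concept: str, value: str):
        super().__init__(f"unmapped value {value!r} for concept {concept!r}")
        self.concept = concept
        self.value = value


class ConfigError(CarepathError):
    """Invalid analysis configuration."""


class NodeRunError(CarepathError):
    """A node-side run aborted (e.g. data-model validation failed)."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class AggregationError(CarepathError):
    """Hub-side bundles cannot be merged (mixed strata, duplicate sites...)."""
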