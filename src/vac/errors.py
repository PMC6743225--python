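"""Exception hierarchy for the vigilance pipeline.

Every anticipated failure mode raises a subclass of :class:`VacError` so
callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""

from __future__ import annotations


class VacError(Exception):
    """Base class for all package errors."""


class FormatError(VacError):
    """A file does not conform to the expected dialect."""


class MissingChannelError(VacError):
    """A named channel required by a downstream step is absent."""

    def __init__(self, channel: str, context: str = ""):
        self.channel = channel
        msg = f"required channel {channel!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ParameterError(VacError):
    """A numeric parameter is out of its valid range."""


class ConfigError(VacError):
    """Pipeline configuration failed validation."""


class EmptyInputError(VacError):
    """The input is too short / empty for the requested operation."""


class EmptyResultError(VacError):
    """An operation produced no output; carries a census of the causes."""

    def __init__(self, message: str, census: dict | None = None):
        self.census = dict(census or {})
        if self.census:
            message += f" (flag census: {self.census})"
        super().__init__(message)


class CalibrationError(VacError):
    """Calibration data is unusable (e.g. no alpha peak above the 1/f trend)."""


class LabelError(VacError):
    """Training labels are degenerate (single class)."""


class UnderdeterminedError(VacError):
    """Too few observations to fit the requested model."""


class PreconditionError(VacError):
    """An operation was invoked before its inputs cover the required span."""


class IncompatibilityError(VacError):
    """A model and a feature vector / montage do not match."""


class ModelIOError(VacError):
    """A model file is truncated, corrupt, or of an unsupported version."""
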