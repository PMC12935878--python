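"""Exception hierarchy for the panicle phenotyping pipeline.

Every stage raises a subclass of :class:`PanicleKitError` so batch
orchestration can degrade gracefully (record the reason, keep going).
"""


class PanicleKitError(Exception):
    """Base class for all pipeline errors."""


class InputFormatError(PanicleKitError):
    """A file could not be read or has the wrong shape/format."""


class CalibrationError(PanicleKitError):
    """The red reference disk could not be located (or is ambiguous)."""


class SegmentationError(PanicleKitError):
    """No panicle foreground found, or a grain ROI yielded no component."""


class ModelError(PanicleKitError):
    """A count-correction model is missing a class or could not be fitted."""


class ConfigError(PanicleKitError):
    """Invalid configuration value (thresholds out of order, unknown variant...)."""


class DomainError(PanicleKitError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
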