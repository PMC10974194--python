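"""Exception hierarchy used across the package."""


class WheatThermError(Exception):
    """Base class for all package-specific errors."""


class FrameFormatError(WheatThermError):
    """A thermal frame file could not be parsed (bad cell, wrong band count, ...)."""


class ValidationError(WheatThermError):
    """A table or configuration failed a structural check."""


class ThresholdError(WheatThermError):
    """No temperature threshold can be defined for the given histogram."""


class IndexDomainError(WheatThermError):
    """An index is undefined for the given inputs (e.g. soil temperature <= 0 degC)."""


class DegenerateFitError(WheatThermError):
    """A regression or correlation is undefined (constant predictor, too few points)."""


class OutOfRegimeWarning(UserWarning):
    """Inputs fall outside the physical regime the index was designed for."""
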