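"""Typed exceptions raised across the package."""


class LoRefineError(Exception):
    """Base class for package errors."""


class InvalidParameterError(LoRefineError, ValueError):
    """An argument is non-finite, out of range, or inconsistent."""


class ShapeMismatchError(InvalidParameterError):
    """Array shapes of the operands do not agree."""


class DegenerateImageError(LoRefineError, ValueError):
    """A correlation score is undefined (zero variance under the mask)."""


class ResourceLimitError(LoRefineError, RuntimeError):
    """A requested enumeration exceeds the configured size cap."""


class RefinementFailedError(LoRefineError, RuntimeError):
    """Per-particle optimization could not produce a defined score."""


class FormatError(LoRefineError, ValueError):
    """A file does not conform to the expected on-disk format."""
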