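"""Exception and warning hierarchy used across the package."""


class EchoError(Exception):
    """Base class for all murineecho errors."""


class FormatError(EchoError):
    """A file could not be parsed as the expected image/ROI format."""


class MetadataError(EchoError):
    """Required calibration metadata (spacing, frame interval) is missing."""


class ValidationError(EchoError, ValueError):
    """A domain object violates one of its invariants."""


class SegmentationError(EchoError):
    """A segmentation stage produced no usable result."""


class EchoWarning(UserWarning):
    """Base class for murineecho warnings."""


class ModeMismatchWarning(EchoWarning):
    """Image mode tag does not match the reader that was asked to load it."""


class UniformCostWarning(EchoWarning):
    """A wall search region has no intensity gradient; trace is unreliable."""


class LibrarySizeWarning(EchoWarning):
    """Fewer atlas registrations than requested for label fusion."""
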