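"""Exception hierarchy."""


class EitgestError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EitgestError):
    """Malformed canonical file (missing header, wrong column layout)."""


class IntegrityError(EitgestError):
    """Data violates dataset invariants (duplicate keys, bad labels)."""


class CorruptFrameError(EitgestError):
    """Frame value vector inconsistent with its measurement schedule."""


class MissingReferenceError(EitgestError):
    """A calibration reference (neutral-gesture frames) is unavailable."""


class DegenerateDataError(EitgestError):
    """Data admits no meaningful fit (e.g. constant values for min-max scaling)."""
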