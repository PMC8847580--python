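"""Exception hierarchy for the eegfp package.

All package-specific failures derive from :class:`EegfpError` so callers can
catch one base class at CLI boundaries.
"""


class EegfpError(Exception):
    """Base class for all eegfp errors."""


class FormatError(EegfpError):
    """A file could not be parsed in the expected format."""


class UnsupportedInputError(EegfpError):
    """Input is syntactically valid but uses an unsupported feature
    (e.g. per-channel sampling rates in an EDF file)."""


class ShapeError(EegfpError):
    """Array dimensions are inconsistent with metadata or with each other."""


class DegenerateSignalError(EegfpError):
    """A constant (flat) channel carries no information and cannot be
    min-max scaled; usually indicates a broken electrode."""


class InsufficientLengthError(EegfpError):
    """A signal is shorter than the window arithmetic requires."""


class ChannelLookupError(EegfpError, KeyError):
    """A requested channel label is not present in a recording/montage."""


class ConfigurationError(EegfpError):
    """Invalid model or run configuration."""


class TrainingError(EegfpError):
    """Training preconditions violated (bad labels, empty classes, ...)."""


class ScorerError(EegfpError):
    """The channel-set scorer could not produce an accuracy."""


class SelectionError(EegfpError):
    """Forward channel selection failed on every candidate."""


class DuplicateIdentityError(EegfpError):
    """Enrolling an identity that already exists without the overwrite flag."""


class UnknownIdentityError(EegfpError):
    """Verification claim for an identity absent from the store."""


class StaleModelError(EegfpError):
    """Fingerprint model version does not match the enrollment store."""


class UndefinedDistanceError(EegfpError):
    """Distance undefined for the given inputs (zero vector under cosine)."""


class UndefinedRateError(EegfpError):
    """FAR/FRR requested on an empty genuine or impostor class."""


class CohortSpecError(EegfpError):
    """Degenerate synthetic cohort specification."""
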