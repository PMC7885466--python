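"""Exception hierarchy.

All domain errors derive from :class:`CloneDropError` so callers can catch
one base class at pipeline boundaries.
"""


class CloneDropError(Exception):
    """Base class for all clonedrop errors."""


class SaturationError(CloneDropError):
    """Every droplet in a channel is positive; the Poisson estimate diverges."""


class EmptyWellError(CloneDropError):
    """A well reports zero droplets."""


class UndefinedFractionError(CloneDropError):
    """Both alleles have zero concentration; the fraction is 0/0."""


class NoReferenceError(CloneDropError):
    """Reference assay concentration is zero; copy number is undefined."""


class DirectionMismatchError(CloneDropError):
    """Measured copy number contradicts the stated gain/loss direction."""


class ModelMismatchError(CloneDropError):
    """Observations cannot be explained by the clone model."""


class UnidentifiableModelError(CloneDropError):
    """The observation set does not identify the clone composition."""

    def __init__(self, message: str, confounded: list[str] | None = None):
        super().__init__(message)
        self.confounded = confounded or []


class InconsistentMeasurementsError(CloneDropError):
    """Derived cell fraction falls outside [0, 1] beyond its CI."""


class PairingError(CloneDropError):
    """DNA/RNA comparison is missing one level or labels do not match."""


class InputValidationError(CloneDropError):
    """Malformed input file; message carries the offending line numbers."""
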