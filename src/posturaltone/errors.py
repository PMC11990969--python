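"""Exception hierarchy shared across the analysis pipeline.

Every rule-based rejection (EMG contamination, missing dorsiflexion phase,
undetectable postural events, ...) raises a distinct subclass so that the
cohort pipeline can log the exclusion reason verbatim.
"""


class PosturalToneError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PosturalToneError):
    """Ill-formed ground-truth or analysis configuration."""


class InstabilityError(ConfigurationError):
    """Inverted-pendulum stiffness does not exceed the gravitational toppling torque."""


class SignalLengthError(PosturalToneError):
    """Signal too short for the requested operation."""


class ValidityError(PosturalToneError):
    """A trial failed a protocol validity rule (EMG activity, velocity constancy)."""


class SegmentationError(PosturalToneError):
    """Requested movement phase not present in the recording."""


class NoEventError(PosturalToneError):
    """Postural-phase landmark (T0/M0/M1) not detectable in the trace."""


class InsufficientDataError(PosturalToneError):
    """Fewer valid repetitions than the protocol requires.

    Carries the per-repetition exclusion reasons in ``exclusions``.
    """

    def __init__(self, message: str, exclusions=None):
        super().__init__(message)
        self.exclusions = list(exclusions or [])


class DegenerateSignalError(PosturalToneError):
    """Signal carries no usable variation (constant series, zero sway)."""


class NormalizationError(PosturalToneError):
    """Baseline RMS is zero; envelope cannot be normalised."""


class UndefinedIndexError(PosturalToneError):
    """Coactivation index undefined (both activities zero)."""


class DomainError(PosturalToneError):
    """Evaluation requested outside a fitted model's domain."""


class NeighbourSearchError(PosturalToneError):
    """Wolf algorithm found no eligible neighbour at some replacement step."""
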