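"""Exception hierarchy shared across the package."""


class CogloadError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CogloadError, ValueError):
    """A configuration value violates its documented range."""


class FormatError(CogloadError, ValueError):
    """A file's layout does not match the expected schema."""


class ValidationError(CogloadError, ValueError):
    """Input data violates an invariant (duplicates, bad labels, ...)."""


class EmptyManifestError(ValidationError):
    """The subject manifest contains no rows."""


class ChannelMissingError(CogloadError, KeyError):
    """A required montage channel is absent from a recording file."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:  # KeyError quotes its arg; keep a sentence
        return f"required montage channel {self.label!r} not found in file"


class NotSiftableError(CogloadError, ValueError):
    """Signal has too few extrema to build upper/lower envelopes."""


class DegenerateInputError(CogloadError, ValueError):
    """An all-zero or otherwise degenerate input makes a ratio undefined."""


class DegenerateMomentError(DegenerateInputError):
    """Zero standard deviation: skewness/kurtosis are undefined."""


class RatioUndefinedError(DegenerateInputError):
    """Adjacent-band partner has zero absolute sum."""


class InsufficientModesError(CogloadError, ValueError):
    """A channel decomposed into fewer modes than the feature layout needs."""


class DegenerateChannelError(CogloadError, ValueError):
    """A zero-variance channel cannot be normalized."""


class InvalidTrainingError(CogloadError, ValueError):
    """Training set lacks both classes or is otherwise unusable."""
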