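"""Exception types raised across the package."""


class FlimputeError(Exception):
    """Base class for all package errors."""


class NoKnownValuesError(FlimputeError):
    """A profile has zero observed entries, so model-based imputation is undefined."""


class ShapeMismatchError(FlimputeError):
    """Feature counts or array lengths disagree between inputs."""


class InvalidInputError(FlimputeError):
    """Non-finite or otherwise malformed numeric input."""


class UnknownMethodError(FlimputeError):
    """An imputation method name is not one of the registered methods."""


class DuplicateIdError(FlimputeError):
    """Sample or feature identifiers are not unique."""
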