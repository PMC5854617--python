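"""Exception hierarchy for survey-data and modelling errors."""


class CascadeSDMError(Exception):
    """Base class for all package-specific errors."""


class DataError(CascadeSDMError, ValueError):
    """Invalid data content (domain violations, bad values)."""


class AlignmentError(DataError):
    """Community and environment tables do not describe the same sites."""


class DomainError(DataError):
    """A value lies outside its permitted domain (e.g. non-binary occurrence)."""


class DegenerateError(DataError):
    """A computation is undefined for this input (zero margin, constant column...)."""


class StratificationError(DataError):
    """A class has too few sites to fill the requested number of folds."""


class SchemaError(DataError, KeyError):
    """A required named column or species is missing."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return ValueError.__str__(self)


class CompositionError(DataError):
    """Cascade parts do not fit together (missing sub-model, etc.)."""


class ConfigError(DataError):
    """Invalid configuration value."""


class NotFittedStateError(CascadeSDMError, RuntimeError):
    """A trained model was required but not available."""
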