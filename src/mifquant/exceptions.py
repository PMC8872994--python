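"""Exception hierarchy for mifquant.

All errors raised by the package derive from :class:`MifquantError` so callers
can catch everything with one clause; the subclasses mirror the distinct
failure modes of the pipeline stages.
"""


class MifquantError(Exception):
    """Base class for all mifquant errors."""


class InvalidParameterError(MifquantError, ValueError):
    """A parameter is outside its documented range or inconsistent."""


class InvalidLibraryError(MifquantError, ValueError):
    """A spectral library is rank-deficient or otherwise unusable."""


class DegenerateSpectrumError(MifquantError, ValueError):
    """A reference image yields an all-zero or undefined spectrum."""


class DegenerateMarkerError(MifquantError, ValueError):
    """A marker's intensity distribution is constant (p1 == p99)."""


class PlacementError(MifquantError, RuntimeError):
    """Random cell placement failed to find a non-overlapping layout."""


class SchemaError(MifquantError, KeyError):
    """A table or record is missing required columns/fields."""


class InvalidInputError(MifquantError, ValueError):
    """Statistical input violates a precondition (e.g. an empty group)."""


class UndefinedCorrelationError(MifquantError, ValueError):
    """Repeated-measures correlation is undefined (no within-subject x variance)."""


class InsufficientDataError(MifquantError, ValueError):
    """Too few observations/subjects for the requested fit (df < 1)."""


class ConfigError(MifquantError, ValueError):
    """Pipeline configuration failed validation; message lists all violations."""


class StageError(MifquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
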