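"""Exception hierarchy.

Errors are grouped into three families so the CLI can map them onto
distinct exit codes: configuration problems, data problems, and
numerical problems.
"""


class AirdmdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AirdmdError):
    """Invalid configuration, spec, or call arguments."""


class DataError(AirdmdError):
    """Malformed, degenerate, or mismatched data."""


class InsufficientDataError(DataError):
    """Too few snapshots/frames for the requested operation."""


class DegenerateDeckError(DataError):
    """A deck whose content is unusable (e.g. all frames near zero)."""


class ShapeMismatchError(DataError):
    """Two decks/distributions do not share the required layout."""


class BinningError(ShapeMismatchError):
    """Two histograms do not share reference point / radius / bin width."""


class MaskLookupError(DataError, KeyError):
    """Requested region mask does not exist."""


class EmptyResultError(DataError):
    """A filter removed every element."""


class NumericalError(AirdmdError):
    """Numerical failure during model fitting or evaluation."""


class RankDeficiencyError(NumericalError):
    """Requested rank exceeds the numerical rank of the data.

    Carries the attainable rank in ``attainable_rank``.
    """

    def __init__(self, message: str, attainable_rank: int):
        super().__init__(message)
        self.attainable_rank = attainable_rank


class ExtrapolationError(ConfigurationError):
    """Target parameter lies outside the trained bracket."""


class CoverageError(ConfigurationError):
    """No pair of trained models brackets the target parameter."""
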