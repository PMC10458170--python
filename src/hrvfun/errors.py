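"""Exception hierarchy for the hrvfun pipeline.

Exit-code mapping used by the CLI: :class:`InputError` and subclasses map to
exit code 2 (malformed or out-of-contract input), :class:`DataQualityError`
to exit code 3 (input was parseable but scientifically unusable).
"""


class HrvFunError(Exception):
    """Base class for all hrvfun errors."""


class InputError(HrvFunError, ValueError):
    """Input violates an operation's contract (bad shape, range, or format)."""


class NoBeatsError(InputError):
    """Fewer than two heartbeats detectable in a PPG trace."""


class DurationError(InputError):
    """Session shorter than one analysis window."""


class UndefinedRatioError(InputError):
    """LF/HF ratio undefined because HF band power is zero."""


class SingularFitError(InputError):
    """Rank-deficient design matrix: the regression has no unique solution."""


class SpecError(InputError):
    """A synthetic-generation spec is invalid or infeasible."""


class ConfigurationError(HrvFunError):
    """Pipeline configuration is incomplete or inconsistent."""


class DataQualityError(HrvFunError):
    """Data parsed correctly but no valid analysis is possible (e.g. every
    segment failed the minimum-beat check)."""
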