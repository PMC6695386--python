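"""Exception hierarchy.

Every error raised by this package derives from :class:`RadVitalError` so
callers (and the CLI) can distinguish validation problems (exit code 2)
from recordings that are simply too short or too quiet to analyse
(exit code 3).
"""


class RadVitalError(Exception):
    """Base class for all radvital errors."""


class InvalidArgumentError(RadVitalError, ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(RadVitalError, ValueError):
    """A recording file or sidecar does not match the on-disk schema."""


class InsufficientDataError(RadVitalError):
    """The recording is too short (or too empty) for the requested analysis."""


class InsufficientBeatsError(InsufficientDataError):
    """Fewer than two pulse peaks were detected."""


class UndefinedStatisticError(RadVitalError):
    """The requested statistic has no defined value for this input
    (e.g. zero variance, degenerate margins)."""
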