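"""Exception hierarchy.

Every error raised by saccadekit derives from :class:`SaccadeKitError` so callers
can catch the package's failures with a single except clause. Input problems
(malformed files, violated invariants) and data problems (too few samples,
degenerate geometry) are distinguished because the CLI maps them to different
exit codes.
"""


class SaccadeKitError(Exception):
    """Base class for all saccadekit errors."""


class ParseError(SaccadeKitError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(SaccadeKitError):
    """Input violates a structural invariant (non-uniform sampling, mixed frame sizes...)."""


class InsufficientDataError(SaccadeKitError):
    """Too few samples/frames/events for the requested operation."""


class DegeneratePathError(SaccadeKitError):
    """A trajectory has zero spatial extent where positive extent is required."""


class DegeneratePredictorError(SaccadeKitError):
    """A regression design matrix is rank deficient."""


class SpecError(SaccadeKitError):
    """A synthetic session/clip specification is internally inconsistent."""


class JoinError(SaccadeKitError):
    """A covariate join key is missing; the message lists the offending ids."""
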