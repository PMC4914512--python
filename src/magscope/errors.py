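"""Exception hierarchy shared across magscope modules."""


class MagscopeError(Exception):
    """Base class for all magscope errors."""


class InvalidParameterError(MagscopeError, ValueError):
    """A parameter is outside its documented domain."""


class SequenceLengthError(MagscopeError, ValueError):
    """A sequence is too short for the requested operation."""


class DegenerateInputError(MagscopeError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all-ambiguous)."""


class TooFewPointsError(MagscopeError, ValueError):
    """Not enough observations to run the requested procedure."""


class InvalidPolygonError(MagscopeError, ValueError):
    """Polygon is degenerate or self-intersecting."""


class InsufficientDataError(MagscopeError, ValueError):
    """Fewer values than the statistic requires."""


class UndefinedCorrelationError(MagscopeError, ValueError):
    """Correlation undefined (zero-variance profile)."""


class MissingDataError(MagscopeError, KeyError):
    """A required record (coverage, metadata, mapping) is absent."""
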