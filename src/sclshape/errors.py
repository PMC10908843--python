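"""Exception hierarchy.

Every error raised by sclshape derives from :class:`SclShapeError`, so callers
can catch one type at pipeline boundaries while tests assert on specific ones.
"""


class SclShapeError(Exception):
    """Base class for all sclshape errors."""


class InvalidParameterError(SclShapeError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class TooShortError(SclShapeError, ValueError):
    """A series or segment is shorter than the operation requires."""


class DegenerateSegmentError(SclShapeError, ValueError):
    """Cleaning or normalization left a segment unusable (e.g. empty)."""


class DegenerateSeriesError(SclShapeError, ValueError):
    """A series has zero norm / zero variance where shape is required."""


class MissingBaselineError(SclShapeError, ValueError):
    """No usable samples in the 5 s pre-script baseline window."""


class InvalidBaselineError(SclShapeError, ValueError):
    """Baseline conductance is non-positive and cannot normalize a segment."""


class MalformedEventsError(SclShapeError, ValueError):
    """Event markers overlap, are out of order, or fall outside the recording."""


class DuplicateRecordError(SclShapeError, ValueError):
    """Two feature records share the same (person, scene, phase) key."""


class InvalidKError(SclShapeError, ValueError):
    """Requested cluster count is outside [2, n_series]."""


class UndefinedScoreError(SclShapeError, ValueError):
    """A validation score is undefined (e.g. silhouette with one cluster)."""


class ConfigError(SclShapeError, ValueError):
    """Pipeline configuration file is malformed or contains unknown keys."""


class ParseError(SclShapeError, ValueError):
    """An input file violates the documented format; message names the row."""
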