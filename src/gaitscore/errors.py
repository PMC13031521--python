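"""Exception hierarchy for the gait-analysis pipeline."""


class GaitScoreError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GaitScoreError, ValueError):
    """A parameter violates its documented domain."""


class ParseError(GaitScoreError, ValueError):
    """Pose file could not be parsed; message names the offending record."""


class FormatError(GaitScoreError, ValueError):
    """Pose file parsed but violates the expected record layout."""


class EmptyInputError(GaitScoreError, ValueError):
    """An operation received no usable data."""


class DegenerateChannelError(GaitScoreError, ValueError):
    """A keypoint or channel carries no usable signal."""


class DegenerateGeometryError(GaitScoreError, ValueError):
    """Coincident points make an angle or ray undefined."""


class AlignmentError(GaitScoreError, ValueError):
    """Channel sets of unequal length cannot be combined."""


class SchemaError(GaitScoreError, KeyError):
    """Feature names, provenance keys or metadata columns do not match."""


class InsufficientDataError(GaitScoreError, ValueError):
    """Too few samples, subjects or classes for the requested analysis."""


class DegenerateFoldError(GaitScoreError, ValueError):
    """A cross-validation training fold contains a single class."""


class ConfigurationError(GaitScoreError, ValueError):
    """A required component (e.g. a pair classifier) is missing."""


class MissingBaselineError(GaitScoreError, ValueError):
    """A patient lacks a baseline visit; message names the patient."""


class UndefinedStatisticError(GaitScoreError, ValueError):
    """A statistic is undefined on this input (e.g. zero-variance truth)."""


class UnstableCIError(GaitScoreError, ValueError):
    """Too many degenerate bootstrap resamples to trust the interval."""
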