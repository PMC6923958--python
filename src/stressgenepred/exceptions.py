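"""Exception hierarchy for stressgenepred.

All errors raised on bad user input derive from :class:`StressGenePredError`
so callers can catch the package's failures with a single except clause.
"""


class StressGenePredError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StressGenePredError, ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class ParseError(StressGenePredError, ValueError):
    """A cell could not be parsed (non-numeric expression value, ...)."""


class ConsistencyError(StressGenePredError, ValueError):
    """Tables disagree with each other or with a vocabulary.

    Examples: an expression sample missing from the metadata table, a stress
    label outside the stress vocabulary, a ranked gene outside the gene
    vocabulary.
    """


class DataError(StressGenePredError, ValueError):
    """A sample violates a data invariant (empty replicate set, NaN value)."""


class ConfigError(StressGenePredError, ValueError):
    """A configuration value is invalid or infeasible."""


class DegenerateSampleError(StressGenePredError, ValueError):
    """A sample has no regulated genes and cannot be normalised/classified."""


class TrainingError(StressGenePredError, RuntimeError):
    """Optimisation produced a non-finite loss or had no usable samples."""
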