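"""Exception hierarchy for koscan.

Every anticipated failure mode maps to a distinct subclass so callers (and
the CLI) can translate error categories into exit codes.
"""


class KoscanError(Exception):
    """Base class for all koscan errors."""


class MalformedSequenceError(KoscanError):
    """A sequence contains characters outside the accepted alphabet."""


class MalformedMotifError(KoscanError):
    """A motif string contains a non-IUPAC symbol."""


class UndefinedInputError(KoscanError):
    """An operation was called on input for which it is undefined (e.g. empty)."""


class UnsupportedKError(KoscanError):
    """k-mer size outside the supported range."""


class InsufficientDataError(KoscanError):
    """Not enough observations to carry out a statistical comparison."""


class UndefinedRatioError(KoscanError):
    """Percentage with a zero denominator."""


class InconsistentCountsError(KoscanError):
    """Campaign counts violate their internal ordering invariants."""


class SchemaError(KoscanError):
    """A table does not conform to the expected column schema."""


class ConfigError(KoscanError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(KoscanError):
    """A simulation step could not produce a valid draw (e.g. lesion > context)."""
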