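"""Exception hierarchy for ncbind.

All library errors derive from :class:`NcbindError` so callers (and the CLI)
can catch one base class; each subclass maps to a distinct failure mode.
"""


class NcbindError(Exception):
    """Base class for all ncbind errors."""


class FastaParseError(NcbindError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


class SequenceValidationError(NcbindError, ValueError):
    """A peptide sequence violates the 20-letter canonical alphabet."""


class LengthError(NcbindError, ValueError):
    """A peptide length falls outside the permitted bounds."""


class DatasetSizeError(NcbindError, ValueError):
    """Not enough samples to satisfy a requested class ratio or split."""


class ConfigurationError(NcbindError, ValueError):
    """An invalid model / generator configuration."""


class TrainingError(NcbindError, ValueError):
    """The dataset cannot be trained on (e.g. only one class present)."""


class DivergenceError(NcbindError, RuntimeError):
    """Training produced a non-finite loss."""


class ShapeError(NcbindError, ValueError):
    """Mismatched array shapes between inputs that must align."""


class UndefinedMetricError(NcbindError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""
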