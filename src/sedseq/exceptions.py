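"""Exception hierarchy for sedseq."""


class SedseqError(Exception):
    """Base class for all sedseq errors."""


class ConfigurationError(SedseqError, ValueError):
    """Invalid generator or pipeline configuration."""


class DomainError(SedseqError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class InputError(SedseqError, ValueError):
    """Malformed or incomplete input data (e.g. a missing spike-in well)."""


class InferenceError(SedseqError, RuntimeError):
    """Statistical inference cannot proceed (e.g. too few usable transcripts)."""


class FitError(SedseqError, RuntimeError):
    """No optimizer start converged for a model fit."""
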