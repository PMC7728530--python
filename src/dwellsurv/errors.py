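"""Exception types shared across the pipeline."""


class DwellsurvError(Exception):
    """Base class for package errors."""


class ConfigurationError(DwellsurvError):
    """A configuration object or file is invalid or inconsistent."""


class InputError(DwellsurvError, ValueError):
    """Input data violate a documented precondition (unsorted trace, negative
    hours, empty required table, ...)."""


class DegenerateInputError(InputError):
    """Statistically degenerate input: all-constant covariate, zero events,
    exactly collinear design."""


class ConvergenceError(DwellsurvError):
    """Iterative fit failed: singular information matrix or monotone partial
    likelihood (complete separation)."""
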