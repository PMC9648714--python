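"""Exception hierarchy shared across the package."""


class XAEError(Exception):
    """Base class for package errors."""


class FormatError(XAEError, ValueError):
    """A delimited input file does not have the documented layout."""


class ValidationError(XAEError, ValueError):
    """Input data violate a structural contract (missing patients, cycles, ...)."""


class TrainingError(XAEError, RuntimeError):
    """Optimisation failed (non-finite loss, degenerate data)."""
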