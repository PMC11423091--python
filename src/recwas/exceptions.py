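"""Exception hierarchy shared across the package."""


class RecwasError(Exception):
    """Base class for all package errors."""


class ParseError(RecwasError, ValueError):
    """Malformed input file (wrong token count, bad coordinates, ...)."""


class ParameterError(RecwasError, ValueError):
    """Invalid argument value (bad MAF bounds, h2 out of range, ...)."""


class DegenerateDataError(RecwasError, ValueError):
    """Input data carry no usable signal (constant response, all-missing
    genotype column, zero-variance genetic component, empty model)."""
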