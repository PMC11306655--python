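"""Exception hierarchy shared across the pipeline.

Stage code raises the most specific class; the CLI maps each class to a
distinct exit code (validation/configuration -> 2, I/O -> 3, numerical -> 4).
"""


class PDFEError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PDFEError, ValueError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(PDFEError, ValueError):
    """Input data violates a precondition (labels, class counts, shapes)."""


class NumericalError(PDFEError, ArithmeticError):
    """A computation produced non-finite values; the message names where."""
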