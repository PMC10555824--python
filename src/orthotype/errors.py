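"""Exception hierarchy.

``ValidationError`` covers malformed configuration or arguments (CLI exit
code 2); ``DataError`` covers inputs that parse but violate the data
contracts (CLI exit code 3).
"""


class OrthotypeError(Exception):
    """Base class for all package errors."""


class ValidationError(OrthotypeError):
    """Invalid configuration, parameters or arguments."""


class DataError(OrthotypeError):
    """Input data violates a contract (format, dimensions, identifiers)."""
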