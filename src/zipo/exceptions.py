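"""Package exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit code 1);
``NumericError`` covers runtime numerical failures such as a non-finite loss
(CLI exit code 2).
"""


class ZipoError(Exception):
    """Base class for package errors."""


class ValidationError(ZipoError):
    """Invalid data, shapes, or configuration."""


class NumericError(ZipoError):
    """A computation produced a non-finite or otherwise invalid value."""
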