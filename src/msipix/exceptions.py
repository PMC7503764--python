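"""Package-wide exception types."""


class MsipixError(Exception):
    """Base class for msipix errors."""


class ParameterError(MsipixError, ValueError):
    """Raised for invalid configuration or operation parameters."""


class DataError(MsipixError, ValueError):
    """Raised when input data violate a structural contract."""
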