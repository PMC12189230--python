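"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violates a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when module parameters are incompatible with the data shapes."""
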