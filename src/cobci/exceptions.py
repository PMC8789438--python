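"""Exception taxonomy: configuration vs parameter vs data problems."""


class CobciError(ValueError):
    """Base class for all toolkit errors."""


class ConfigurationError(CobciError):
    """Invalid simulation / training / experiment configuration."""


class ParameterError(CobciError):
    """Invalid numeric parameter to an operation (e.g. filter band edges)."""


class DataError(CobciError):
    """Input data violates a structural contract (missing markers, shapes)."""
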