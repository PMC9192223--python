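"""Exception types shared across the package."""


class MimodesError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MimodesError, ValueError):
    """Input too short, empty, or otherwise unusable for the operation."""


class EnvelopeError(MimodesError, ValueError):
    """Too few extrema to fit upper/lower envelopes; treat signal as residual."""


class ConfigurationError(MimodesError, ValueError):
    """Invalid configuration value; the message names the offending key."""
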