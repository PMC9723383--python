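"""Exception hierarchy shared by all TLsub modules."""


class TLsubError(Exception):
    """Base class for all TLsub errors."""


class VCFFormatError(TLsubError, ValueError):
    """Input is not a parseable VCF (missing or garbled header, bad line)."""


class FeatureExtractionError(TLsubError, ValueError):
    """A VCF field expected to be numeric could not be converted."""


class ConfigurationError(TLsubError, ValueError):
    """An invalid parameter value (latent dimension, simulation config, ...)."""


class DimensionError(TLsubError, ValueError):
    """Mismatched matrix/vector shapes between pipeline stages."""
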