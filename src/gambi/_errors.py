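class GambiError(ValueError):
    """Base class for domain errors raised by this package."""


class IndexNotComputableError(GambiError):
    """Raised when no assigned taxa remain, so the index is undefined."""


class AzoicSampleError(GambiError):
    """Raised when an azoic sample reaches an operation that cannot handle it."""
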