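"""Exception types shared across the package."""


class LongmethError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LongmethError, ValueError):
    """Inputs are structurally inconsistent (mismatched ids, bad pairing, ...)."""


class ConfigurationError(LongmethError, ValueError):
    """Required fields or settings are missing or unusable."""


class IncompleteRegionError(LongmethError, KeyError):
    """A region refers to probes with no per-probe test result."""


class InsufficientPairsError(LongmethError, ValueError):
    """Not enough same-chromosome probe pairs to estimate spatial correlation."""
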