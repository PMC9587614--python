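"""Exception hierarchy shared across the package."""


class LtdrScanError(Exception):
    """Base class for all package-specific errors."""


class InputError(LtdrScanError, ValueError):
    """Malformed or out-of-contract input data (bad alphabet, empty sequence...)."""


class ConfigError(LtdrScanError, ValueError):
    """Invalid parameter combination (e.g. min_len > max_len)."""


class PlacementError(LtdrScanError):
    """A simulated insertion collides with a previously planted locus."""


class IOFormatError(LtdrScanError, ValueError):
    """A file does not parse as the expected format."""
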