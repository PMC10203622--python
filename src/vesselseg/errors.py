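"""Package exception types."""


class ConfigurationError(ValueError):
    """An invalid generator/network/training configuration."""


class DimensionError(ValueError):
    """Array dimensions incompatible with the requested operation."""


class DataLayoutError(FileNotFoundError):
    """A dataset directory does not match the expected layout."""
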