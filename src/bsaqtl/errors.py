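"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid genetic map, trait model, or read model."""


class DataError(ValueError):
    """Malformed input data (inconsistent counts, unsorted sites, ...)."""
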