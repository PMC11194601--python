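"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (bad counts, degenerate intervals, bad windows)."""


class FormatError(ValueError):
    """A file does not conform to the expected format."""
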