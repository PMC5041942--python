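"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class InputError(ValueError):
    """Arguments violate an operation's preconditions."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""
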