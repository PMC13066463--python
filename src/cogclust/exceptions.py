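"""Package exceptions."""


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class InputError(ValueError):
    """Input data violates a precondition of an operation."""
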