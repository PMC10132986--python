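"""Package exceptions."""


class TumortimeError(Exception):
    """Base class for package errors."""


class ConfigError(TumortimeError):
    """An invalid configuration field; the message names the field."""


class DomainError(TumortimeError):
    """An argument outside the mathematical domain of an operation."""
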