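"""Exception types shared across the pipeline."""


class MatrisomeScanError(Exception):
    """Base class for all package errors."""


class FormatError(MatrisomeScanError):
    """An input file violates its dialect or a table violates its invariants."""


class ConfigError(MatrisomeScanError):
    """A configuration value is out of range or inconsistent."""


class EmptyGroupError(MatrisomeScanError):
    """A two-group comparison was requested with an empty group."""
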