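"""Exception types shared across the pipeline."""


class NeurodynError(Exception):
    """Base class for package errors."""


class SchemaError(NeurodynError):
    """An input table/file is missing a required column or is malformed."""


class ConfigError(NeurodynError):
    """A configuration value is out of its documented range."""


class ComputationError(NeurodynError):
    """A computation cannot proceed on the given data (degenerate input)."""
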