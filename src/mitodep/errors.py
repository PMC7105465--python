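"""Exception hierarchy shared across the pipeline stages."""


class MitodepError(Exception):
    """Base class for all package errors."""


class ConfigError(MitodepError):
    """A configuration value violates its documented constraint."""


class InputError(MitodepError):
    """An input table is inconsistent with its companion tables."""


class SchemaError(MitodepError):
    """A table on disk does not match its declared schema."""


class NormalizationError(MitodepError):
    """A run cannot be normalized (e.g. no peptides shared with the reference)."""


class ValidationError(MitodepError):
    """A record violates a per-field invariant (names the offending record)."""
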