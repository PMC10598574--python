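"""Exception hierarchy shared across the package."""


class SynergraphError(Exception):
    """Base class for all package errors."""


class FormatError(SynergraphError):
    """A file does not conform to its expected layout (missing columns, bad header)."""


class ValidationError(SynergraphError):
    """Well-formed input violating a semantic invariant (duplicate ids, bad references)."""


class FeaturizationError(SynergraphError):
    """A molecule or sequence could not be featurized."""


class ConfigError(SynergraphError):
    """Invalid or inconsistent run configuration."""
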