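"""Exception hierarchy shared across the package."""


class UnresError(Exception):
    """Base class for all package errors."""


class SchemaError(UnresError):
    """A required column or metadata entry is missing or misnamed."""


class IntegrityError(UnresError):
    """Input data violates a structural invariant (duplicates, non-binary values, ...)."""


class ConfigError(UnresError):
    """A configuration value is out of its valid range."""


class DegenerateInputError(UnresError):
    """A statistic is undefined for the given input (e.g. pooled SD of zero)."""


class InputError(UnresError):
    """Inputs are individually valid but jointly unusable (e.g. no shared cell lines)."""
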