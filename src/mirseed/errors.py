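"""Exception hierarchy shared across the package."""


class MirseedError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MirseedError):
    """Input violates a documented precondition (bad alphabet, bad range...)."""


class ParseError(MirseedError):
    """A file could not be parsed (malformed FASTA/TSV record)."""


class SchemaError(MirseedError):
    """A tabular input is missing required columns."""


class SingularDesignError(MirseedError):
    """A regression design matrix is rank deficient or the response is degenerate."""


class ConfigError(MirseedError):
    """A run configuration is inconsistent (e.g. housekeeper assay absent)."""
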