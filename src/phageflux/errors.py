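"""Exception hierarchy shared across the pipeline."""


class PhagefluxError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(PhagefluxError):
    """Sequences that should form an alignment do not (ragged lengths, bad residues)."""


class MetadataError(PhagefluxError):
    """Sample identifiers or labels are inconsistent with the data."""


class InputError(PhagefluxError):
    """Malformed or empty input."""


class DegenerateInputError(PhagefluxError):
    """Input is structurally valid but carries no usable signal."""


class ConfigError(PhagefluxError):
    """Invalid configuration value."""


class SelectionError(PhagefluxError):
    """A requested data slice is empty."""
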