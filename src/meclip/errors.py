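"""Exception hierarchy shared across the pipeline."""


class MeclipError(Exception):
    """Base class for all package errors."""


class InputError(MeclipError, ValueError):
    """Invalid user-supplied value (bad range, non-finite number, ...)."""


class FormatError(MeclipError, ValueError):
    """Malformed file content (FASTA/TSV/BED parsing problems)."""


class ConsistencyError(MeclipError, ValueError):
    """Inputs that are individually valid but disagree with each other,
    e.g. a SAM alignment against a transcript absent from the reference."""


class ConfigError(MeclipError, ValueError):
    """Invalid parameter combination in a configuration object."""


class PlacementError(MeclipError, RuntimeError):
    """Requested number of sites cannot be placed under the spacing rule."""
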