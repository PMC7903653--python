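"""Exception hierarchy shared across the pipeline stages."""


class DDSNError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(DDSNError, ValueError):
    """Malformed OBO input; the message names the offending line."""


class FormatError(DDSNError, ValueError):
    """Malformed tabular input; the message names the offending row."""


class UnknownTermError(DDSNError, KeyError):
    """A term (or node) identifier is absent from the relevant structure."""


class CycleError(DDSNError, ValueError):
    """The is_a graph is not acyclic; the message lists one cycle."""


class ConfigurationError(DDSNError, ValueError):
    """Inputs or parameters that make the requested computation undefined."""


class ComputationError(DDSNError, ValueError):
    """An internal inconsistency detected mid-computation (e.g. missing IC)."""
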