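"""Exception hierarchy shared across the pipeline.

``InputError`` marks problems with user-supplied data (malformed matrices,
label mismatches); ``ConfigurationError`` marks invalid parameter
combinations. The CLI maps these to distinct exit codes.
"""


class MetasigError(Exception):
    """Base class for all package-specific errors."""


class InputError(MetasigError, ValueError):
    """User-supplied data is malformed or inconsistent."""


class ConfigurationError(MetasigError, ValueError):
    """A parameter set violates its invariants."""


class EmptyResultError(MetasigError):
    """A pipeline stage produced an empty result (e.g. no candidate genes)."""
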