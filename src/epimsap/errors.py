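"""Exception hierarchy shared across the package."""


class EpimsapError(Exception):
    """Base class for all package errors."""


class FormatError(EpimsapError):
    """A tabular input violates its expected layout or value domain."""


class ConfigError(EpimsapError):
    """A configuration value is missing, unknown or out of range."""


class AnalysisError(EpimsapError):
    """A statistical routine received input it cannot analyse."""
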