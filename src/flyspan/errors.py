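"""Exception types shared across the package."""


class FlyspanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FlyspanError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(FlyspanError, ValueError):
    """Malformed input file; message names the offending row/column."""


class AnalysisError(FlyspanError, ValueError):
    """Analysis preconditions violated (e.g. too few lines for top-k)."""
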