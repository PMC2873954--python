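"""Exception hierarchy for cghdiv."""


class CghdivError(Exception):
    """Base class for all cghdiv errors."""


class ConfigurationError(CghdivError):
    """Invalid generator or pipeline configuration."""


class FormatError(CghdivError):
    """Malformed input file (missing columns, bad records)."""


class PreprocessingError(CghdivError):
    """Background correction or filtering failed."""


class NormalizationError(CghdivError):
    """Within-array loess normalization could not be performed."""


class AnalysisError(CghdivError):
    """Statistical analysis failed (degenerate input, rank deficiency)."""
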