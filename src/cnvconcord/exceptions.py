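"""Exception hierarchy shared across the pipeline stages."""


class CnvConcordError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CnvConcordError):
    """Invalid configuration value or combination."""


class SizingError(ConfigError):
    """Requested genome too small to host the requested genes/regions."""


class ProbeDesignError(CnvConcordError):
    """A gene cannot host the requested number of non-overlapping probes."""


class DataError(CnvConcordError):
    """Malformed or inconsistent input data (named in the message)."""


class InsufficientDataError(CnvConcordError):
    """Too few observations or groups for the requested statistic."""
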