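"""Exception hierarchy shared by all modules."""


class RoikstError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RoikstError):
    """A user-supplied configuration value is invalid (bad column name,
    unknown marker id, out-of-range simulation parameter, ...)."""


class DataError(RoikstError):
    """The data themselves violate a contract (out-of-range values,
    empty sample intersection, rank-deficient design, ...)."""
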