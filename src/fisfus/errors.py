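"""Exception types shared across the package."""


class FisFusError(Exception):
    """Base class for all package errors."""


class FormatError(FisFusError, ValueError):
    """A file did not match the documented CSV dialect."""


class DataError(FisFusError, ValueError):
    """Input data violate a precondition (e.g. non-monotone timestamps)."""


class ConfigError(FisFusError, ValueError):
    """A configuration value is invalid (e.g. r_in > r_out)."""


class ScriptError(FisFusError, ValueError):
    """A simulation script violates its invariants."""
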