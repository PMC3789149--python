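"""Exception types shared across the package."""


class PhytolatticeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhytolatticeError, ValueError):
    """A simulation configuration value is missing, unknown or out of range."""


class InfeasibleParametersError(PhytolatticeError, ValueError):
    """A requested community cannot be constructed (e.g. pivot above b_max)."""


class BracketFailureError(PhytolatticeError, RuntimeError):
    """A threshold scan found no persistence anywhere on the grid."""


class IncomparableStatesError(PhytolatticeError, ValueError):
    """Two lattice states differ too much in density to be compared."""
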