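"""Exception hierarchy for netconsensus."""


class NetConsensusError(Exception):
    """Base class for all package errors."""


class FormatError(NetConsensusError, ValueError):
    """Malformed or inconsistent input data (files or matrices)."""


class ConfigError(NetConsensusError, ValueError):
    """Invalid algorithm or generator configuration."""


class DataError(NetConsensusError, ValueError):
    """Score/outcome tables that cannot support the requested analysis."""


class NumericalError(NetConsensusError, RuntimeError):
    """Iterative solver failed to converge."""


class RandomizationError(NetConsensusError, RuntimeError):
    """Degree-preserving randomization could not find a valid matching."""
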