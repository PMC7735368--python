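"""Exception hierarchy for data validation and fitting failures."""


class OtterNbdaError(Exception):
    """Base class for all package-specific errors."""


class InputError(OtterNbdaError):
    """Malformed or empty input file / value (e.g. negative event time)."""


class IdentityError(OtterNbdaError):
    """A record references an individual id absent from the roster."""


class ConsistencyError(OtterNbdaError):
    """Internally contradictory records (duplicate acquisition, individual
    in two parties within one scan, solve before first interaction)."""


class ConfigurationError(OtterNbdaError):
    """Invalid analysis configuration (unknown ILV, empty model space,
    non-partition grouping)."""


class DegenerateNetworkError(OtterNbdaError):
    """Network cannot be built (singleton roster)."""


class UndefinedCoefficientError(OtterNbdaError):
    """Social differentiation undefined (mean association index is zero)."""


class InsufficientOverlapError(OtterNbdaError):
    """Matrix comparison requested with fewer than three shared individuals."""


class FitError(OtterNbdaError):
    """Numerical optimisation failed to converge on every start."""
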