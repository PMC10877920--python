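"""Exception hierarchy used across the package."""


class DHurdleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DHurdleError):
    """A configuration object violates its invariants."""


class ParameterDomainError(DHurdleError):
    """A model parameter lies outside its admissible domain (sigma <= 0, |rho| >= 1)."""


class DataError(DHurdleError):
    """Input data violate the contract (unknown category, negative outcome, ...)."""


class ContractError(DHurdleError):
    """Mismatched shapes/objects passed between pipeline stages."""


class DegenerateDataError(DataError):
    """Outcome is all-zero or all-positive; the double hurdle is not identified."""
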