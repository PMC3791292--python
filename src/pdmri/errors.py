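"""Exception hierarchy for the pdmri package."""


class PDMRIError(Exception):
    """Base class for all pdmri errors."""


class FormatError(PDMRIError, ValueError):
    """A file does not conform to the expected text dialect."""


class ValidationError(PDMRIError, ValueError):
    """Data violate a structural invariant (negative signal, duplicate key, ...)."""


class ContractError(PDMRIError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(PDMRIError, ValueError):
    """Input is structurally valid but statistically degenerate (zero variance, all-zero signal)."""


class ConfigurationError(PDMRIError, ValueError):
    """A cohort configuration is internally inconsistent or infeasible."""
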