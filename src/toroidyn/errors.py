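"""Exception hierarchy for toroidyn."""


class ToroidynError(Exception):
    """Base class for all toroidyn errors."""


class ConfigurationError(ToroidynError):
    """A rate parameter, geometry value or config entry violates its contract."""


class SchemaError(ConfigurationError):
    """A configuration file does not match the published schema."""


class TruncationError(ToroidynError):
    """Mean-field length truncation leaked more mass than the allowed bound."""


class NumericalError(ToroidynError):
    """Propensity or ODE right-hand side became non-finite."""


class InfeasibleShapeError(ToroidynError):
    """No spherocylinder of the required length exists under the constraint."""

    def __init__(self, message: str, max_length_nm: float | None = None):
        super().__init__(message)
        self.max_length_nm = max_length_nm
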