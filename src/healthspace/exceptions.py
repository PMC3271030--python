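"""Exception hierarchy shared across the package."""


class HealthSpaceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HealthSpaceError):
    """A configuration value or file is invalid (unknown parameter, bad proportions...)."""


class InsufficientDataError(HealthSpaceError):
    """Too few subjects / pairs / clusters to carry out the requested operation."""


class MissingDataError(HealthSpaceError):
    """A required value is absent and cannot be imputed."""


class MissingParameterError(ConfigurationError):
    """A parameter required by an axis definition is not present in the table."""

    def __init__(self, parameters):
        self.parameters = list(parameters)
        super().__init__(f"missing parameters: {', '.join(self.parameters)}")


class DegenerateAxisError(HealthSpaceError):
    """An axis whose treated and control mean scores coincide cannot be anchored."""
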