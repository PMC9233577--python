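"""Exception hierarchy shared across the package."""


class AghdstratError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AghdstratError):
    """A configuration file or parameter set is invalid (CLI exit code 2)."""


class InputDataError(AghdstratError):
    """Input data violate a structural precondition (CLI exit code 3)."""


class InvalidCodeError(ConfigurationError):
    """A clinical code is empty or un-normalizable."""


class EmptyCohortError(InputDataError):
    """A statistic was requested on an empty cohort."""
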