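"""Exception hierarchy for the cvdprevent model."""


class CVDPreventError(Exception):
    """Base class for all model errors."""


class ConfigurationError(CVDPreventError):
    """A configuration value is invalid; the message names the field."""


class ParameterError(CVDPreventError):
    """A required model parameter (e.g. a risk-equation coefficient) is missing."""


class CalibrationError(CVDPreventError):
    """Risk calibration could not be performed; the message lists the cells."""


class DomainError(CVDPreventError):
    """An input is outside the mathematical domain of an operation."""


class NumericalValidityError(CVDPreventError):
    """A computed transition probability left [0, 1]; names stratum and cycle."""


class ConsistencyError(CVDPreventError):
    """Results being combined were produced against different comparators."""
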