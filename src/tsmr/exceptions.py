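"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DegenerateDataError`` to
exit code 3. ``ContractViolationError`` signals a caller bug, never bad data.
"""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """Invalid run configuration (bad column map, unreadable input, ...)."""


class ColumnMapError(ConfigurationError):
    """A mapped column is missing from the input header."""


class DegenerateDataError(TsmrError):
    """Data that is syntactically fine but cannot support the analysis."""


class EmptyInputError(DegenerateDataError):
    """An input table contains zero valid rows."""


class NoSharedInstrumentsError(DegenerateDataError):
    """Exposure and outcome tables share no usable SNPs."""


class InsufficientInstrumentsError(DegenerateDataError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(DegenerateDataError):
    """An instrument with zero exposure effect but nonzero weight."""


class CollinearityError(DegenerateDataError):
    """No variation in oriented exposure effects; regression undefined."""


class LDInformationRequiredError(DegenerateDataError):
    """Co-located SNP pair lacks an r-squared entry during clumping."""


class ContractViolationError(TsmrError):
    """An operation was called outside its documented precondition."""


class DomainError(TsmrError, ValueError):
    """Numeric argument outside the mathematical domain of an operation."""
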