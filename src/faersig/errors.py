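"""Exception hierarchy.

ConfigError -> CLI exit code 2; DataError and subclasses -> exit code 3.
"""


class FaersigError(Exception):
    """Base class for all package errors."""


class ConfigError(FaersigError):
    """Invalid user configuration (dictionaries, simulation or study config)."""


class DataError(FaersigError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """A quarterly file's header does not match any known column schema."""


class CaseNotFoundError(DataError, KeyError):
    """A primaryid was requested that no bundle contains."""


class DialectError(DataError):
    """A value cannot be represented in the '$'-delimited dialect."""


class SeparationError(FaersigError):
    """Logistic fit failed: complete/quasi-complete separation or non-convergence."""


class EnumerationLimitError(FaersigError):
    """Exact r x c enumeration would exceed the table-count guard."""
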