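"""Exception hierarchy shared across the pipeline.

Each class maps to a CLI exit code: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class RamanDxError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RamanDxError):
    """Invalid configuration (schema violation, inconsistent parameters)."""

    exit_code = 2


class DataError(RamanDxError):
    """Invalid or inconsistent input data (shape mismatch, unknown label...)."""

    exit_code = 3


class NumericalError(RamanDxError):
    """Numerical failure during computation (NaN loss, non-finite input...)."""

    exit_code = 4
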