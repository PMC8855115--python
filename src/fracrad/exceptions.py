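"""Package-specific exception types.

Plain ``ValueError``/``IndexError`` are raised for ordinary argument-domain
violations; the classes here mark errors a pipeline driver may want to
catch and report separately.
"""


class FracradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FracradError, ValueError):
    """A parameter table, model spec, or run configuration is unusable."""


class DataFormatError(FracradError, ValueError):
    """An input file violates the documented column/row contract."""


class NumericalError(FracradError, RuntimeError):
    """A simulation or linear-algebra step produced non-finite values."""


class UndefinedMetricError(FracradError, ValueError):
    """A correlation metric is undefined for the given vectors (e.g. zero variance)."""
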