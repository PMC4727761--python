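"""Exception hierarchy for the ftirquant pipeline.

The CLI maps these onto distinct exit codes (config=2, data=3, numeric=4).
"""


class FTIRQuantError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(FTIRQuantError):
    """Invalid pipeline configuration or recipe."""


class DataError(FTIRQuantError):
    """Invalid, inconsistent, or unreadable input data."""


class SpectrumParseError(DataError):
    """A spectrum file could not be parsed."""


class UnitError(DataError):
    """A spectrum file declares units the pipeline cannot consume."""


class CoverageError(DataError):
    """A target grid extends beyond a spectrum's measured range."""


class NumericError(FTIRQuantError):
    """A numerical precondition is violated (rank, variance, shape...)."""
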