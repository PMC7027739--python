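"""Exception hierarchy for the microsoc package."""


class MicrosocError(Exception):
    """Base class for all package errors."""


class MeasurementError(MicrosocError, ValueError):
    """A raw measurement violates its physical preconditions.

    Raised for non-positive soil mass / time / temperature / pressure /
    headspace volume, negative CO2 flux, negative isotopic excess in strict
    mode, fumigated extract below the unfumigated one in strict mode,
    non-positive DNA content, and similar physically impossible inputs.
    """


class UndefinedValueError(MicrosocError, ValueError):
    """A derived quantity is mathematically undefined for the given input.

    Examples: CUE when growth and respiration are both zero, turnover time
    for non-positive biomass-specific growth, a fungal:bacterial ratio with
    zero bacterial necromass, a correlation with a zero-variance variable.
    """


class SchemaError(MicrosocError, ValueError):
    """An input table is missing required columns (names are reported)."""


class DesignError(MicrosocError, ValueError):
    """The experimental design is degenerate (e.g. an empty block)."""


class GraphError(MicrosocError, ValueError):
    """A path model is structurally invalid (e.g. contains a cycle)."""


class FitError(MicrosocError, RuntimeError):
    """A statistical model failed to fit (rank deficiency, non-convergence)."""


class ConfigError(MicrosocError, ValueError):
    """A synthetic-data or pipeline configuration is infeasible or invalid."""
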