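"""Physical constants used by the measurement conversions."""

from dataclasses import dataclass

from .errors import MeasurementError


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the gas-law and isotope-tracer conversions.

    Attributes
    ----------
    R : float
        Ideal gas constant, J mol^-1 K^-1.
    M_C : float
        Molar mass of carbon, g/mol.
    f_O_DNA : float
        Mass fraction of oxygen in double-stranded DNA, percent.  Used to
        convert the oxygen pool of a DNA extract into a DNA mass.
    """

    R: float = 8.314
    M_C: float = 12.01
    f_O_DNA: float = 31.21

    def __post_init__(self) -> None:
        if self.R <= 0 or self.M_C <= 0 or self.f_O_DNA <= 0:
            raise MeasurementError("physical constants must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()
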