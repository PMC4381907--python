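"""Physical constants used in voltage-dependent rate laws."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant, and absolute temperature.

    Defaults are CODATA values at room temperature (298.15 K).  The only
    combination the model uses is the thermal voltage RT/F (~25.7 mV at
    298.15 K), which sets the voltage scale of every exp(zFV/RT) factor.
    """

    F: float = 96485.332  # C/mol
    R: float = 8.31446  # J/(mol K)
    T: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.F <= 0 or self.R <= 0 or self.T <= 0:
            raise ValueError("physical constants must be positive")

    @property
    def thermal_voltage_mv(self) -> float:
        """RT/F in millivolts."""
        return 1000.0 * self.R * self.T / self.F


DEFAULT_CONSTANTS = PhysicalConstants()
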