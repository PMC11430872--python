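"""Physical constants used across the thermodynamic calculations.

Values are CODATA; they are module-level defaults and can be overridden by
passing an explicit :class:`PhysicalConstants` where a function accepts one.
"""

from dataclasses import dataclass

R_J_PER_MOL_K = 8.314
BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34


@dataclass(frozen=True)
class PhysicalConstants:
    R_J_per_molK: float = R_J_PER_MOL_K
    boltzmann_J_per_K: float = BOLTZMANN_J_PER_K
    planck_J_s: float = PLANCK_J_S

    def __post_init__(self) -> None:
        if self.R_J_per_molK <= 0 or self.boltzmann_J_per_K <= 0 or self.planck_J_s <= 0:
            raise ValueError("physical constants must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()
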