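"""Physical constants, unit conversions and instrument defaults."""

from __future__ import annotations

from dataclasses import dataclass

BOLTZMANN_J_PER_K = 1.380649e-23

#: Molar mass of the yeast alcohol dehydrogenase tetramer (g/mol); all molar
#: protein concentrations in this package are per ~150 kDa tetramer.
DEFAULT_PROTEIN_MOLAR_MASS = 150_000.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Instrument and sample constants shared across the pipeline.

    Defaults follow a He-Ne DLS setup (632.8 nm, 90 degree detection) and a
    150 kDa tetrameric protein.
    """

    k_B: float = BOLTZMANN_J_PER_K          # J/K
    wavelength: float = 632.8               # nm
    scatter_angle: float = 90.0             # degrees
    protein_molar_mass: float = DEFAULT_PROTEIN_MOLAR_MASS  # g/mol

    def __post_init__(self) -> None:
        for name in ("k_B", "wavelength", "scatter_angle", "protein_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def celsius_to_kelvin(T_celsius: float) -> float:
    return T_celsius + 273.15


def protein_molarity(conc_mg_ml: float, molar_mass: float = DEFAULT_PROTEIN_MOLAR_MASS) -> float:
    """Molar concentration (mol/L) of a protein given mg/mL and g/mol.

    mg/mL equals g/L, so this is ``conc / molar_mass``.  0.4 mg/mL of a
    150 kDa tetramer is 2.67e-6 mol/L.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if conc_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    return conc_mg_ml / molar_mass
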