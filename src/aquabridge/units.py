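"""Physical constants and unit conversions.

Internal conventions: lengths in Å, times in ps, charges in elementary
charges (e), electrostatic potential in kT/e.  Diffusion constants cross the
API boundary in cm²/s, dipole moments in debye, concentrations in mol/l.
"""

from __future__ import annotations

# CODATA 2018
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
AVOGADRO = 6.02214076e23

#: 1 debye in e·Å
DEBYE_TO_E_ANGSTROM = 0.2081943

#: cm²/s -> Å²/ps  (1 cm² = 1e16 Å², 1 s = 1e12 ps)
CM2_PER_S_TO_A2_PER_PS = 1.0e4
A2_PER_PS_TO_CM2_PER_S = 1.0e-4

#: mol/l -> molecules per Å³
MOLAR_TO_PER_A3 = AVOGADRO / 1.0e27


def bjerrum_length_vacuum(temperature: float) -> float:
    """Vacuum Bjerrum length e²/(4πε₀kT) in Å.

    This is the single electrostatic coupling constant of the lattice solver:
    with ϕ in kT/e and lengths in Å, Poisson's equation reads
    ∇·(ε_r ∇ϕ) = −4π·λ_B0·ρ with ρ in e/Å³.  ≈557 Å at 300 K.
    """
    lb_m = ELEMENTARY_CHARGE_C**2 / (
        4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY * BOLTZMANN_J_PER_K * temperature
    )
    return lb_m * 1.0e10
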