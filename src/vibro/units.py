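"""Physical constants and unit conversions used throughout the package.

Internal conventions: Hessians, electric fields and multipoles in Hartree
atomic units; geometry I/O in Angstrom; masses in amu; vibrational
frequencies in cm^-1; MD energies in kcal/mol.  Every conversion factor is
derived from CODATA values via :mod:`scipy.constants` so that round trips
(au -> kcal/mol -> au, etc.) are exact to machine precision.
"""

from __future__ import annotations

import math

from scipy import constants as _c

# ---- base CODATA quantities (SI) ----
HARTREE_J = _c.physical_constants["Hartree energy"][0]
BOHR_M = _c.physical_constants["Bohr radius"][0]
AMU_KG = _c.atomic_mass
ELECTRON_MASS_KG = _c.m_e
HBAR_JS = _c.hbar
KB_J = _c.k
AVOGADRO = _c.N_A
C_M_S = _c.c
E_CHARGE = _c.e
EPS0 = _c.epsilon_0

# ---- lengths ----
BOHR_PER_ANGSTROM = 1e-10 / BOHR_M
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# ---- masses ----
AMU_PER_ME = AMU_KG / ELECTRON_MASS_KG  # ~1822.888

# ---- energies ----
KCALMOL_PER_HARTREE = HARTREE_J * AVOGADRO / (_c.calorie * 1000.0)
HARTREE_PER_KCALMOL = 1.0 / KCALMOL_PER_HARTREE
EV_PER_HARTREE = HARTREE_J / E_CHARGE
KCALMOL_PER_EV = E_CHARGE * AVOGADRO / (_c.calorie * 1000.0)
J_PER_KCALMOL = _c.calorie * 1000.0 / AVOGADRO  # per molecule

# gas constant in the paper's working units, kcal/(mol K)
R_KCALMOL_K = _c.R / (_c.calorie * 1000.0)

# ---- spectroscopy ----
# 1 cm^-1 in various units
CM1_J = _c.h * C_M_S * 100.0  # photon energy of a 1 cm^-1 quantum
MEV_PER_CM1 = CM1_J / E_CHARGE * 1000.0  # ~0.123984
CM1_PER_EV = 1.0 / (MEV_PER_CM1 / 1000.0)
KCALMOL_PER_CM1 = CM1_J * AVOGADRO / (_c.calorie * 1000.0)

# atomic unit of time and angular frequency
AU_TIME_S = HBAR_JS / HARTREE_J

# Hessian eigenvalue (Hartree / Bohr^2 / amu) -> harmonic wavenumber (cm^-1):
# omega = sqrt(lambda) in SI, nu~ = omega / (2 pi c)
_EIG_SI = HARTREE_J / (BOHR_M**2 * AMU_KG)  # 1/s^2 per (Eh/Bohr^2/amu)
WAVENUMBER_PER_SQRT_EIG = math.sqrt(_EIG_SI) / (2.0 * math.pi * C_M_S * 100.0)


def wavenumber_from_eigenvalue(eigval: float) -> float:
    """Signed harmonic wavenumber (cm^-1) from a mass-weighted Hessian
    eigenvalue in Hartree/(Bohr^2 amu); negative eigenvalues map to
    negative (imaginary) wavenumbers."""
    return math.copysign(math.sqrt(abs(eigval)) * WAVENUMBER_PER_SQRT_EIG, eigval)


def angular_frequency_au(wavenumber_cm1: float) -> float:
    """Angular frequency in atomic units (1/au-time) from a wavenumber."""
    omega_si = 2.0 * math.pi * C_M_S * 100.0 * wavenumber_cm1
    return omega_si * AU_TIME_S


# IR intensity prefactor: |d mu / dQ|^2 in (e / sqrt(amu))^2 -> km/mol.
# A(km/mol) = N_A pi / (3 c^2 4 pi eps0) * (e^2/amu) |dmu/dQ|^2 / 1000
IR_KM_MOL_PER_E2_AMU = (
    AVOGADRO * E_CHARGE**2 / (12.0 * EPS0 * C_M_S**2 * AMU_KG) / 1000.0
)

# Coulomb constant for MD-style electrostatics, kcal*Angstrom/(mol e^2)
COULOMB_KCAL_A_E2 = (
    E_CHARGE**2 / (4.0 * math.pi * EPS0 * 1e-10) * AVOGADRO / (_c.calorie * 1000.0)
)
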