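"""Electron-phonon coupling of an odorant's vibrations to an electron
transfer event in the surrounding receptor.

The chain is: the receptor's redox state i in {donor, acceptor} creates a
local electric field E_i at the odorant; the field displaces the atoms by
Delta(E_i, n); the displacement projects onto each normal mode mu as the
mass-weighted normal-coordinate shift

    dPi_mu(E_i) = sum_n m(n) y_mu(n) . Delta(E_i, n)    [amu^1/2 Bohr]

giving a dimensionless coupling strength per mode and state

    u_i(mu) = - sqrt(omega_mu / (2 hbar)) * dPi_mu(E_i)

(evaluated in atomic units), and finally the Huang-Rhys factors of the
displaced harmonic oscillator,

    S = (u_D - u_A)^2,   sigma_n = S^n exp(-S) / n!

— a normalized Poisson distribution over the number n of vibrational
quanta emitted during the transfer.  sigma_1 is the single-phonon weight
relevant to inelastic tunnelling.

Two interchangeable routes produce Delta: linear response of the harmonic
molecule to the field acting on its partial charges, or the difference of
two externally optimized geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import units
from .embedding_field import FieldMap
from .molecular_io import HessianData, Molecule
from .normal_modes import NormalModes, eckart_vectors


@dataclass
class DisplacementSet:
    """Per-atom Cartesian displacements Delta(E_i, n) in Bohr."""

    vectors: np.ndarray  # (N, 3), Bohr
    provenance: str  # 'linear_response' | 'geometry_difference'
    state: str = "donor"

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacements must be finite")


@dataclass
class CouplingTable:
    """Per-mode coupling results for a donor/acceptor pair of field states."""

    frequencies: np.ndarray  # cm^-1
    dpi_donor: np.ndarray  # amu^1/2 Bohr
    dpi_acceptor: np.ndarray
    u_donor: np.ndarray  # dimensionless
    u_acceptor: np.ndarray
    huang_rhys_s: np.ndarray  # S = (u_D - u_A)^2
    sigma: np.ndarray  # (n_modes, n_max + 1): sigma_n per mode
    metadata: dict = field(default_factory=dict)

    @property
    def sigma1(self) -> np.ndarray:
        """Single-phonon emission weight per mode."""
        return self.sigma[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": np.arange(1, len(self.frequencies) + 1),
            "frequency_cm1": self.frequencies,
            "dpi_donor": self.dpi_donor,
            "dpi_acceptor": self.dpi_acceptor,
            "u_donor": self.u_donor,
            "u_acceptor": self.u_acceptor,
            "S": self.huang_rhys_s,
            "sigma1": self.sigma1,
        })


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

def displacements_linear_response(hessian: HessianData, field_map: FieldMap,
                                  molecule: Optional[Molecule] = None
                                  ) -> DisplacementSet:
    """Harmonic (linear-response) displacement of the molecule in a field.

    The field exerts a force F_n = q_n E(n) on each partial charge; the
    equilibrium shift solves H Delta = F restricted to the internal
    subspace: the Eckart-projected mass-weighted Hessian is pseudo-inverted
    so that rigid-body components are annihilated rather than amplified.
    Output in Bohr, guaranteed translation/rotation-free.
    """
    mol = molecule or hessian.molecule
    if mol.charges is None:
        raise ValueError("molecule carries no partial charges; linear-response "
                         "displacements need q_n to build forces q_n E(n)")
    if field_map.points.shape[0] != mol.n_atoms:
        raise ValueError("field map must have one vector per atom")

    forces = (mol.charges[:, None] * field_map.vectors).ravel()  # Hartree/Bohr
    m = np.repeat(mol.masses, 3)
    sqm = np.sqrt(m)
    h_mw = hessian.matrix / np.outer(sqm, sqm)
    tr = eckart_vectors(mol)
    p = np.eye(len(m)) - tr.T @ tr
    h_proj = p @ h_mw @ p

    evals, evecs = np.linalg.eigh(0.5 * (h_proj + h_proj.T))
    n_internal = len(m) - tr.shape[0]
    thresh = max(1e-12, 1e-10 * np.abs(evals).max())
    nonzero = np.abs(evals) > thresh
    if nonzero.sum() < n_internal:
        raise np.linalg.LinAlgError(
            f"Hessian is singular beyond the {tr.shape[0]} rigid-body modes "
            f"({n_internal - int(nonzero.sum())} extra zero eigenvalues)")
    inv = np.where(nonzero, 1.0 / np.where(nonzero, evals, 1.0), 0.0)
    f_mw = p @ (forces / sqm)
    delta_mw = evecs @ (inv * (evecs.T @ f_mw))  # sqrt(amu) Bohr
    delta = (delta_mw / sqm).reshape(mol.n_atoms, 3)  # Bohr
    return DisplacementSet(delta, "linear_response", state=field_map.state)


def displacements_from_geometries(ref: Molecule, displaced: Molecule,
                                  state: str = "donor") -> DisplacementSet:
    """Displacements as the difference of two geometries (Angstrom in,
    Bohr out) after mass-weighted rigid-body superposition of the displaced
    structure onto the reference (Eckart-like alignment)."""
    if ref.n_atoms != displaced.n_atoms:
        raise ValueError("geometries have different atom counts")
    w = ref.masses
    a = ref.coords - np.average(ref.coords, axis=0, weights=w)
    b = displaced.coords - np.average(displaced.coords, axis=0, weights=w)
    rot = _kabsch(b, a, w)
    delta_ang = a - b @ rot.T
    return DisplacementSet(-delta_ang * units.BOHR_PER_ANGSTROM,
                           "geometry_difference", state=state)


def _kabsch(moving: np.ndarray, target: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Kabsch rotation R minimizing sum w |R.moving - target|^2
    over proper rotations (both sets pre-centered)."""
    h = (w[:, None] * moving).T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


# ---------------------------------------------------------------------------
# mode projections and couplings
# ---------------------------------------------------------------------------

def mode_shift(modes: NormalModes, disp: DisplacementSet) -> np.ndarray:
    """Mass-weighted normal-coordinate shifts dPi_mu = sum_n m(n) y_mu(n) .
    Delta(n), in amu^1/2 Bohr (displacements already in Bohr)."""
    if disp.vectors.shape[0] != modes.molecule.n_atoms:
        raise ValueError("displacement set does not match the molecule")
    m = modes.molecule.masses
    return np.einsum("n,mni,ni->m", m, modes.vectors, disp.vectors)


def coupling_strength(frequency_cm1, dpi) -> np.ndarray:
    """Dimensionless coupling u = -sqrt(omega / 2 hbar) dPi, evaluated in
    atomic units (hbar = 1): omega converted from cm^-1 to inverse atomic
    time, dPi from amu^1/2 Bohr to electron-mass^1/2 Bohr."""
    frequency_cm1 = np.asarray(frequency_cm1, dtype=float)
    dpi = np.asarray(dpi, dtype=float)
    if np.any(frequency_cm1 <= 0):
        raise ValueError("coupling strengths need positive (real) frequencies; "
                         "exclude imaginary/rigid-body modes upstream")
    omega_au = np.vectorize(units.angular_frequency_au)(frequency_cm1)
    dpi_au = dpi * math.sqrt(units.AMU_PER_ME)
    return -np.sqrt(omega_au / 2.0) * dpi_au


def huang_rhys(u_donor, u_acceptor, n_max: int = 10,
               normalized: bool = True):
    """Huang-Rhys factors sigma_0..sigma_n_max from the two coupling
    strengths.

    With S = (u_D - u_A)^2 the default (normalized) form is the Poisson
    weight sigma_n = S^n exp(-S) / n!, which sums to one over all n.
    ``normalized=False`` evaluates the divergent variant with exp(+S)
    instead, retained only for comparison.
    Returns ``(S, sigma)`` with sigma of shape (..., n_max + 1).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    u_donor = np.asarray(u_donor, dtype=float)
    u_acceptor = np.asarray(u_acceptor, dtype=float)
    s = (u_donor - u_acceptor) ** 2
    n = np.arange(n_max + 1)
    log_fact = np.cumsum(np.log(np.maximum(n, 1)))
    sign = -1.0 if normalized else 1.0
    with np.errstate(divide="ignore"):
        log_sn = n * np.log(np.where(s[..., None] > 0, s[..., None], 1.0))
    log_sn = np.where((s[..., None] == 0) & (n > 0), -np.inf, log_sn)
    sigma = np.exp(log_sn - log_fact + sign * s[..., None])
    return s, sigma


def couple(modes: NormalModes, disp_donor: DisplacementSet,
           disp_acceptor: DisplacementSet, n_max: int = 10) -> CouplingTable:
    """Full per-mode coupling table for a donor/acceptor displacement pair.

    Imaginary-frequency modes are excluded (with a warning) before the
    coupling stage.
    """
    real = modes.real_modes()
    dpi_d = mode_shift(real, disp_donor)
    dpi_a = mode_shift(real, disp_acceptor)
    u_d = coupling_strength(real.frequencies, dpi_d)
    u_a = coupling_strength(real.frequencies, dpi_a)
    s, sigma = huang_rhys(u_d, u_a, n_max=n_max)
    return CouplingTable(real.frequencies, dpi_d, dpi_a, u_d, u_a, s, sigma,
                         metadata={"n_max": n_max,
                                   "provenance": (disp_donor.provenance,
                                                  disp_acceptor.provenance)})
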