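"""Harmonic vibrational analysis from Cartesian Hessians.

Diagonalizes the mass-weighted Hessian with explicit Eckart projection of
the six rigid-body degrees of freedom, computes double-harmonic IR
intensities from dipole derivatives, matches vacuum and embedded mode
sets by optimal assignment, and renders Lorentzian-broadened spectra.

Conventions: frequencies in cm^-1 (imaginary modes reported as negative
numbers), Cartesian mode vectors y_mu(n) normalized so that
sum_n m(n) |y_mu(n)|^2 = 1 (units amu^-1/2), each eigenvector's sign fixed
so its largest-magnitude component is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import units
from .molecular_io import HessianData, Molecule

logger = logging.getLogger(__name__)

#: modes with |frequency| below this are treated as rigid-body remnants
RIGID_BODY_THRESHOLD_CM1 = 1.0


@dataclass
class NormalModes:
    """Result of a harmonic analysis.

    ``frequencies``: (n_modes,) cm^-1, ascending, imaginary negative.
    ``vectors``: (n_modes, N, 3) Cartesian displacement patterns y_mu(n),
    mass-weight-normalized (amu^-1/2).
    ``reduced_masses``: (n_modes,) amu.
    ``intensities``: (n_modes,) km/mol or None until computed.
    """

    frequencies: np.ndarray
    vectors: np.ndarray
    molecule: Molecule
    reduced_masses: np.ndarray = None
    intensities: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.reduced_masses is None:
            self.reduced_masses = 1.0 / np.einsum("mni->m", self.vectors**2)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def mass_weighted_vectors(self) -> np.ndarray:
        """Orthonormal eigenvectors L_mu(n) = sqrt(m_n) y_mu(n), (n_modes, 3N)."""
        sqm = np.sqrt(self.molecule.masses)[None, :, None]
        return (self.vectors * sqm).reshape(self.n_modes, -1)

    def real_modes(self) -> "NormalModes":
        """Drop imaginary-frequency modes (with a warning) for the coupling
        and spectrum stages, which assume real frequencies."""
        keep = self.frequencies > 0
        if not keep.all():
            logger.warning("excluding %d imaginary mode(s) from analysis",
                           int((~keep).sum()))
        return NormalModes(self.frequencies[keep], self.vectors[keep],
                           self.molecule, self.reduced_masses[keep],
                           None if self.intensities is None
                           else self.intensities[keep], dict(self.metadata))


@dataclass
class ModeMatch:
    """One-to-one assignment between vacuum and embedded mode sets."""

    vacuum_indices: np.ndarray
    embedded_indices: np.ndarray
    overlaps: np.ndarray  # squared mass-weighted overlap per pair, in [0, 1]
    shifts_cm1: np.ndarray  # nu_embedded - nu_vacuum
    shifts_mev: np.ndarray


def eckart_vectors(molecule: Molecule) -> np.ndarray:
    """Orthonormal translation/rotation vectors in mass-weighted Cartesian
    coordinates, shape (k, 3N) with k = 5 for linear molecules, else 6."""
    m = molecule.masses
    x = molecule.coords - molecule.center_of_mass()
    sqm = np.sqrt(m)
    n = molecule.n_atoms
    vecs = []
    for axis in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, axis] = sqm
        vecs.append(v.ravel())
    for axis in range(3):  # rotations: sqrt(m) * (r x e_axis)
        e = np.zeros(3)
        e[axis] = 1.0
        v = sqm[:, None] * np.cross(x, e)
        vecs.append(v.ravel())
    basis = np.array(vecs).T  # (3N, 6)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep].T


def compute_normal_modes(hessian: HessianData, project_tr: bool = True) -> NormalModes:
    """Diagonalize the mass-weighted Hessian.

    With ``project_tr`` the Eckart translation/rotation subspace is
    projected out before diagonalization and the rigid-body eigenvalues
    (numerically < 1 cm^-1) are discarded, leaving 3N-6 (3N-5 for linear
    molecules) internal modes.  Negative eigenvalues are reported as
    negative frequencies with a warning.
    """
    mol = hessian.molecule
    m = np.repeat(mol.masses, 3)
    h_mw = hessian.matrix / np.sqrt(np.outer(m, m))  # Hartree/Bohr^2/amu
    n_tr = 0
    if project_tr:
        tr = eckart_vectors(mol)
        n_tr = tr.shape[0]
        p = np.eye(len(m)) - tr.T @ tr
        h_mw = p @ h_mw @ p
    evals, evecs = np.linalg.eigh(0.5 * (h_mw + h_mw.T))
    if not np.all(np.isfinite(evals)):
        raise ValueError("non-finite eigenvalues in mass-weighted Hessian")

    freqs = np.array([units.wavenumber_from_eigenvalue(ev) for ev in evals])
    if project_tr:
        rigid = np.abs(freqs) < RIGID_BODY_THRESHOLD_CM1
        if rigid.sum() > n_tr:
            logger.warning(
                "%d near-zero modes after projecting %d rigid-body vectors; "
                "geometry may not be a stationary point", int(rigid.sum()), n_tr)
        keep = ~rigid
        freqs, evecs = freqs[keep], evecs[:, keep]
    if np.any(freqs < 0):
        logger.warning("%d imaginary frequencies (reported negative)",
                       int((freqs < 0).sum()))

    order = np.argsort(freqs)
    freqs, evecs = freqs[order], evecs[:, order]
    # sign convention: largest-|component| of each eigenvector positive
    for k in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    # Cartesian mode vectors y = M^{-1/2} L ; then sum m |y|^2 = |L|^2 = 1
    y = (evecs / np.sqrt(m)[:, None]).T.reshape(len(freqs), mol.n_atoms, 3)
    return NormalModes(freqs, y, mol,
                       metadata={"projected": project_tr, "n_rigid": n_tr})


def ir_intensities(modes: NormalModes, molecule: Optional[Molecule] = None) -> NormalModes:
    """Double-harmonic IR intensities (km/mol) from per-atom dipole
    derivatives: A_mu proportional to |sum_n (dmu/dr_n) . y_mu(n)|^2."""
    molecule = molecule or modes.molecule
    if molecule.dipole_derivatives is None:
        raise ValueError(
            "molecule carries no dipole-derivative tensors; supply them "
            "(Molecule.dipole_derivatives, shape (N, 3, 3), atomic units)")
    # dmu/dQ_mu [e / sqrt(amu)]: derivative tensor (au = e, dimensionless
    # per unit length ratio) contracted with the amu^-1/2 mode pattern
    dmudq = np.einsum("nab,mnb->ma", molecule.dipole_derivatives, modes.vectors)
    modes.intensities = units.IR_KM_MOL_PER_E2_AMU * np.einsum(
        "ma,ma->m", dmudq, dmudq)
    return modes


def match_modes(vacuum: NormalModes, embedded: NormalModes) -> ModeMatch:
    """Pair vacuum and embedded modes by maximizing total squared
    mass-weighted overlap (a linear assignment problem); report the
    frequency shifts Delta-nu = nu_embedded - nu_vacuum in cm^-1 and meV."""
    if vacuum.molecule.n_atoms != embedded.molecule.n_atoms:
        raise ValueError("mode sets refer to molecules of different size")
    lv = vacuum.mass_weighted_vectors()
    le = embedded.mass_weighted_vectors()
    overlap2 = (lv @ le.T) ** 2  # in [0, 1] by orthonormality
    rows, cols = linear_sum_assignment(-overlap2)
    shifts = embedded.frequencies[cols] - vacuum.frequencies[rows]
    return ModeMatch(rows, cols, overlap2[rows, cols], shifts,
                     shifts * units.MEV_PER_CM1)


def broaden_spectrum(modes: NormalModes, fwhm: float,
                     grid: np.ndarray) -> np.ndarray:
    """Lorentzian-broadened spectrum on ``grid`` (cm^-1).

    Each stick contributes intensity * (fwhm/2pi) / ((x-x0)^2 + (fwhm/2)^2),
    a unit-area Lorentzian scaled by the stick intensity, so the integrated
    curve conserves the summed stick intensity on a wide grid.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    inten = modes.intensities if modes.intensities is not None \
        else np.ones(modes.n_modes)
    hwhm = fwhm / 2.0
    lo, hi = grid.min(), grid.max()
    if np.all((modes.frequencies < lo) | (modes.frequencies > hi)):
        logger.warning("no modes inside the spectral grid; flat curve")
    x = grid[:, None] - modes.frequencies[None, :]
    return (inten[None, :] * (hwhm / np.pi) / (x**2 + hwhm**2)).sum(axis=1)
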