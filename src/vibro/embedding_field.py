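"""Electric fields from a distributed-multipole, optionally polarizable,
environment.

The environment is a set of sites carrying a monopole, a point dipole, a
traceless (Buckingham) quadrupole and an anisotropic dipole-dipole
polarizability.  Fields are evaluated in atomic units at arbitrary points;
site positions and evaluation points are supplied in Angstrom and
converted to Bohr internally.  The embedded molecule's own multipoles
never contribute to the field acting on it — only environment sites do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .units import BOHR_PER_ANGSTROM
from .molecular_io import Molecule

logger = logging.getLogger(__name__)


@dataclass
class MultipoleEnvironment:
    """Sites of an embedding potential: positions (Angstrom), monopoles (e),
    dipoles (au), traceless quadrupoles (au), symmetric polarizability
    tensors (au); ``state`` labels the redox state ('donor'/'acceptor')."""

    positions: np.ndarray  # (M, 3) Angstrom
    charges: np.ndarray  # (M,)
    dipoles: Optional[np.ndarray] = None  # (M, 3)
    quadrupoles: Optional[np.ndarray] = None  # (M, 3, 3), traceless
    polarizabilities: Optional[np.ndarray] = None  # (M, 3, 3), symmetric
    state: str = "donor"
    induced_dipoles: Optional[np.ndarray] = None  # set by induce_dipoles

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        m = self.n_sites
        self.charges = np.asarray(self.charges, dtype=float).reshape(m)
        if self.dipoles is None:
            self.dipoles = np.zeros((m, 3))
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(m, 3)
        if self.quadrupoles is None:
            self.quadrupoles = np.zeros((m, 3, 3))
        self.quadrupoles = np.asarray(self.quadrupoles, dtype=float).reshape(m, 3, 3)
        if self.polarizabilities is None:
            self.polarizabilities = np.zeros((m, 3, 3))
        self.polarizabilities = np.asarray(
            self.polarizabilities, dtype=float).reshape(m, 3, 3)
        if np.abs(self.polarizabilities - self.polarizabilities.transpose(0, 2, 1)).max() > 1e-10:
            raise ValueError("polarizability tensors must be symmetric")
        # enforce traceless Buckingham quadrupoles
        traces = np.trace(self.quadrupoles, axis1=1, axis2=2)
        if np.abs(traces).max() > 1e-8:
            logger.warning("removing quadrupole trace (max |tr| = %.3e au)",
                           np.abs(traces).max())
        self.quadrupoles = self.quadrupoles - (
            traces[:, None, None] / 3.0) * np.eye(3)[None]

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def total_dipoles(self) -> np.ndarray:
        """Permanent plus induced dipoles (au)."""
        if self.induced_dipoles is None:
            return self.dipoles
        return self.dipoles + self.induced_dipoles

    def combined_with(self, other: "MultipoleEnvironment") -> "MultipoleEnvironment":
        """Union of two environments (permanent multipoles only)."""
        return MultipoleEnvironment(
            positions=np.vstack([self.positions, other.positions]),
            charges=np.concatenate([self.charges, other.charges]),
            dipoles=np.vstack([self.total_dipoles, other.total_dipoles]),
            quadrupoles=np.vstack([self.quadrupoles, other.quadrupoles]),
            polarizabilities=np.vstack(
                [self.polarizabilities, other.polarizabilities]),
            state=self.state,
        )


@dataclass
class FieldMap:
    """Electric field vectors (au) at evaluation points (Angstrom), one per
    odorant atom, for one redox state."""

    points: np.ndarray  # (N, 3) Angstrom
    vectors: np.ndarray  # (N, 3) au
    state: str = "donor"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.points.shape != self.vectors.shape:
            raise ValueError("one field vector is required per point")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field vectors must be finite")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


# ---------------------------------------------------------------------------
# field evaluation
# ---------------------------------------------------------------------------

def _pairwise_r(points_bohr: np.ndarray, sites_bohr: np.ndarray):
    """Separation vectors R = point - site, (N, M, 3), and distances."""
    rvec = points_bohr[:, None, :] - sites_bohr[None, :, :]
    r = np.linalg.norm(rvec, axis=2)
    return rvec, r


def field_at_points(env: MultipoleEnvironment, points: np.ndarray,
                    include_induced: bool = True,
                    min_distance: float = 1e-6) -> FieldMap:
    """Evaluate the environment's electric field (au) at ``points`` (Angstrom).

    Sums the charge, dipole and traceless-quadrupole contributions of every
    site.  Induced dipoles, when previously converged with
    :func:`induce_dipoles`, are added to the permanent ones unless
    ``include_induced`` is False.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p = points * BOHR_PER_ANGSTROM
    s = env.positions * BOHR_PER_ANGSTROM
    rvec, r = _pairwise_r(p, s)
    too_close = r < min_distance * BOHR_PER_ANGSTROM
    if np.any(too_close):
        i, j = np.argwhere(too_close)[0]
        raise ValueError(
            f"evaluation point {i} coincides with environment site {j} "
            f"(distance {r[i, j]:.3e} Bohr)")

    inv_r3 = r**-3
    # charges: q R / r^3
    E = np.einsum("m,nmk,nm->nk", env.charges, rvec, inv_r3)
    dip = env.total_dipoles if include_induced else env.dipoles
    if np.any(dip != 0):
        E += _dipole_field(dip, rvec, r)
    if np.any(env.quadrupoles != 0):
        # phi = (1/2) R^T Theta R / r^5 ;  E = -grad phi
        tr = np.einsum("mkl,nml->nmk", env.quadrupoles, rvec)  # Theta . R
        rtr = np.einsum("nmk,nmk->nm", rvec, tr)  # R^T Theta R
        E += np.einsum("nm,nmk->nk", 2.5 * rtr * r**-7, rvec) \
            - np.einsum("nm,nmk->nk", r**-5, tr)
    return FieldMap(points, E, state=env.state)


def _dipole_field(dip: np.ndarray, rvec: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Field of point dipoles: (3 (p.R) R / r^5 - p / r^3), summed over sites."""
    pr = np.einsum("mk,nmk->nm", dip, rvec)
    return np.einsum("nm,nmk->nk", 3.0 * pr * r**-5, rvec) \
        - np.einsum("mk,nm->nk", dip, r**-3)


def potential_at_points(env: MultipoleEnvironment, points: np.ndarray,
                        include_induced: bool = True) -> np.ndarray:
    """Electrostatic potential (au) of the environment at points (Angstrom);
    the analytic scalar whose negative gradient :func:`field_at_points`
    returns — useful for consistency checks."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p = points * BOHR_PER_ANGSTROM
    s = env.positions * BOHR_PER_ANGSTROM
    rvec, r = _pairwise_r(p, s)
    phi = np.einsum("m,nm->n", env.charges, 1.0 / r)
    dip = env.total_dipoles if include_induced else env.dipoles
    phi += np.einsum("mk,nmk,nm->n", dip, rvec, r**-3)
    tr = np.einsum("mkl,nml->nmk", env.quadrupoles, rvec)
    phi += 0.5 * np.einsum("nmk,nmk,nm->n", rvec, tr, r**-5)
    return phi


# ---------------------------------------------------------------------------
# self-consistent induced dipoles
# ---------------------------------------------------------------------------

def induce_dipoles(env: MultipoleEnvironment, tol: float = 1e-8,
                   max_iter: int = 200) -> MultipoleEnvironment:
    """Converge induced dipoles mu_i = alpha_i E_i self-consistently under
    mutual dipole-dipole interaction (no Thole damping).

    E_i is the field at site i from every other site's permanent multipoles
    plus the current induced dipoles.  Returns a new environment carrying
    the converged ``induced_dipoles``; raises on non-convergence (the
    polarization catastrophe regime).
    """
    if np.all(env.polarizabilities == 0):
        return replace(env, induced_dipoles=np.zeros((env.n_sites, 3)))

    s = env.positions * BOHR_PER_ANGSTROM
    rvec, r = _pairwise_r(s, s)
    np.fill_diagonal(r, np.inf)  # no self-interaction

    inv_r3 = r**-3
    # permanent field at each site from all the others
    E_perm = np.einsum("m,nmk,nm->nk", env.charges, rvec, inv_r3)
    E_perm += _dipole_field_masked(env.dipoles, rvec, r)
    if np.any(env.quadrupoles != 0):
        tr = np.einsum("mkl,nml->nmk", env.quadrupoles, rvec)
        rtr = np.einsum("nmk,nmk->nm", rvec, tr)
        E_perm += np.einsum("nm,nmk->nk", 2.5 * rtr * r**-7, rvec) \
            - np.einsum("nm,nmk->nk", r**-5, tr)

    mu = np.einsum("nkl,nl->nk", env.polarizabilities, E_perm)
    for _ in range(max_iter):
        E_ind = _dipole_field_masked(mu, rvec, r)
        mu_new = np.einsum("nkl,nl->nk", env.polarizabilities, E_perm + E_ind)
        resid = np.abs(mu_new - mu).max()
        mu = mu_new
        if resid < tol:
            return replace(env, induced_dipoles=mu)
    raise RuntimeError(
        f"induced dipoles did not converge in {max_iter} iterations "
        f"(residual {resid:.3e} au); check for polarization catastrophe")


def _dipole_field_masked(dip: np.ndarray, rvec: np.ndarray,
                         r: np.ndarray) -> np.ndarray:
    """Dipole field with infinite diagonal distances masking self terms."""
    if not np.any(dip != 0):
        return np.zeros((rvec.shape[0], 3))
    return _dipole_field(dip, rvec, r)


# ---------------------------------------------------------------------------
# field differences and averages
# ---------------------------------------------------------------------------

def field_difference(map_a: FieldMap, map_b: FieldMap,
                     atol: float = 1e-9) -> FieldMap:
    """Pointwise difference map_a - map_b between two redox states.

    The returned map's ``meta`` carries the mean difference vector over
    points and its magnitude (the quantity quoted as the field change
    accompanying electron transfer).
    """
    if map_a.points.shape != map_b.points.shape or \
            np.abs(map_a.points - map_b.points).max() > atol:
        raise ValueError("field maps are defined on different points")
    diff = map_a.vectors - map_b.vectors
    mean_vec = diff.mean(axis=0)
    return FieldMap(map_a.points, diff,
                    state=f"{map_a.state}-{map_b.state}",
                    meta={"mean_vector": mean_vec,
                          "mean_magnitude": float(np.linalg.norm(mean_vec)),
                          "mean_of_magnitudes": float(
                              np.linalg.norm(diff, axis=1).mean())})


def mean_field_at_center(fmap: FieldMap, molecule: Molecule,
                         weighting: str = "mass") -> tuple[np.ndarray, float]:
    """Average field vector 'at the center' of a molecule: the mass-weighted
    (default) or plain mean of the per-atom field vectors; returns the
    vector and its magnitude in au."""
    if fmap.points.shape[0] != molecule.n_atoms:
        raise ValueError("field map must have one point per molecule atom")
    if weighting == "mass":
        w = molecule.masses / molecule.masses.sum()
    elif weighting == "geometric":
        w = np.full(molecule.n_atoms, 1.0 / molecule.n_atoms)
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    vec = w @ fmap.vectors
    return vec, float(np.linalg.norm(vec))
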