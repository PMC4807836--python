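"""Synthetic inputs with known ground truth for every pipeline stage.

These generators stand in for the production molecular-dynamics and
quantum-chemistry data of a receptor/odorant study: small harmonic
molecules with exactly known Hessians and analytic frequencies, two-state
point-multipole environments differing by a transferred unit charge,
Gaussian two-state potential-energy traces with chosen means and widths,
and toy trajectories with scripted rigid-body motion plus noise.  Each
generator attaches its own ground truth (analytic modes, generating
parameters, expected series) so downstream tests never re-derive it.

All randomness flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import units
from .embedding_field import MultipoleEnvironment
from .molecular_io import EnergyTrace, HessianData, Molecule
from .traj_analysis import Trajectory


@dataclass
class ToySpec:
    """Recipe for a harmonic toy molecule.

    ``topology``: 'diatomic' | 'linear_triatomic' | 'bent_triatomic' |
    'chain-N' | 'cluster-N' (N an integer, e.g. 'chain-4', 'cluster-17').
    ``k_bond`` (Hartree/Bohr^2) and ``k_bend`` (Hartree/Bohr^2 for the
    perpendicular-bend springs of linear chains, Hartree/rad^2 for the
    bent-triatomic angle) are the force constants; ``bond_length`` in
    Angstrom.  Charges default to an alternating +q/-q pattern that gives
    every toy a nonzero dipole derivative; the dipole-derivative tensor
    defaults to the point-charge model d(mu_a)/d(r_nb) = q_n delta_ab.
    """

    topology: str = "diatomic"
    masses: Optional[list[float]] = None  # amu
    k_bond: float = 0.3
    k_bend: float = 0.05
    bond_length: float = 1.2
    angle_deg: float = 104.5  # bent triatomic only
    charges: Optional[list[float]] = None  # e
    charge_magnitude: float = 0.3
    seed: int = 0

    def n_atoms(self) -> int:
        if self.topology == "diatomic":
            return 2
        if self.topology in ("linear_triatomic", "bent_triatomic"):
            return 3
        if self.topology.startswith(("chain-", "cluster-")):
            return int(self.topology.split("-")[1])
        raise ValueError(f"unsupported topology: {self.topology!r}")


def _bond_block(hess: np.ndarray, i: int, j: int, k: float,
                coords_bohr: np.ndarray) -> None:
    """Add a harmonic bond spring k along the i-j direction (outer product
    of the bond-length gradient; exact at equilibrium)."""
    u = coords_bohr[j] - coords_bohr[i]
    u = u / np.linalg.norm(u)
    grad = np.zeros(hess.shape[0])
    grad[3 * i : 3 * i + 3] = -u
    grad[3 * j : 3 * j + 3] = u
    hess += k * np.outer(grad, grad)


def _perp_bend_blocks(hess: np.ndarray, i: int, j: int, k_idx: int,
                      kb: float, axis: np.ndarray) -> None:
    """Perpendicular-bend springs for a linear i-j-k triple: harmonic in
    the two transverse components of (r_i - 2 r_j + r_k); well defined at
    the linear geometry where the angle gradient vanishes."""
    for perp in _orthonormal_complement(axis):
        grad = np.zeros(hess.shape[0])
        grad[3 * i : 3 * i + 3] = perp
        grad[3 * j : 3 * j + 3] = -2.0 * perp
        grad[3 * k_idx : 3 * k_idx + 3] = perp
        hess += kb * np.outer(grad, grad)


def _orthonormal_complement(axis: np.ndarray) -> list[np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(axis, ref)
    p1 /= np.linalg.norm(p1)
    return [p1, np.cross(axis, p1)]


def _angle_gradient(coords_bohr: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """Gradient of the i-j-k valence angle (rad/Bohr), standard formula."""
    a = coords_bohr[i] - coords_bohr[j]
    b = coords_bohr[k] - coords_bohr[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos_t = a @ b / (na * nb)
    sin_t = math.sqrt(max(1.0 - cos_t**2, 1e-14))
    da = (cos_t * a / na - b / nb) / (na * sin_t)
    db = (cos_t * b / nb - a / na) / (nb * sin_t)
    grad = np.zeros(3 * len(coords_bohr))
    grad[3 * i : 3 * i + 3] = da
    grad[3 * k : 3 * k + 3] = db
    grad[3 * j : 3 * j + 3] = -(da + db)
    return grad


def make_toy_molecule(spec: ToySpec) -> tuple[Molecule, HessianData, dict]:
    """Build a toy molecule, its exact harmonic Hessian and its analytic
    ground truth.

    Returns ``(molecule, hessian, truth)`` where ``truth`` holds the seed,
    whether the geometry is linear, the internal mode count, and — where a
    closed form exists (diatomic; stretches of the symmetric linear
    triatomic) — the analytic frequencies in cm^-1.
    """
    n = spec.n_atoms()
    masses = np.asarray(spec.masses if spec.masses is not None
                        else [1.0] * n, dtype=float)
    if len(masses) != n:
        raise ValueError(f"{n} masses required for topology {spec.topology!r}")
    q = spec.charge_magnitude
    charges = np.asarray(spec.charges if spec.charges is not None
                         else [q * (-1) ** i for i in range(n)], dtype=float)

    b = spec.bond_length
    linear = False
    hess = np.zeros((3 * n, 3 * n))
    truth: dict = {"seed": spec.seed, "topology": spec.topology}

    if spec.topology == "diatomic":
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, b]])
        cb = coords * units.BOHR_PER_ANGSTROM
        _bond_block(hess, 0, 1, spec.k_bond, cb)
        linear = True
        mu = masses[0] * masses[1] / masses.sum()
        truth["analytic_frequencies_cm1"] = [
            units.wavenumber_from_eigenvalue(spec.k_bond / mu)]
    elif spec.topology == "linear_triatomic":
        coords = np.array([[0, 0, -b], [0, 0, 0], [0, 0, b]], dtype=float)
        cb = coords * units.BOHR_PER_ANGSTROM
        _bond_block(hess, 0, 1, spec.k_bond, cb)
        _bond_block(hess, 1, 2, spec.k_bond, cb)
        _perp_bend_blocks(hess, 0, 1, 2, spec.k_bend, np.array([0.0, 0.0, 1.0]))
        linear = True
        if masses[0] == masses[2]:
            m, big = masses[0], masses[1]
            truth["analytic_frequencies_cm1"] = sorted([
                units.wavenumber_from_eigenvalue(spec.k_bond / m),
                units.wavenumber_from_eigenvalue(
                    spec.k_bond * (1.0 / m + 2.0 / big)),
            ])
    elif spec.topology == "bent_triatomic":
        th = math.radians(spec.angle_deg)
        coords = np.array([
            [b * math.sin(th / 2), 0.0, b * math.cos(th / 2)],
            [0.0, 0.0, 0.0],
            [-b * math.sin(th / 2), 0.0, b * math.cos(th / 2)],
        ])
        cb = coords * units.BOHR_PER_ANGSTROM
        _bond_block(hess, 0, 1, spec.k_bond, cb)
        _bond_block(hess, 1, 2, spec.k_bond, cb)
        g = _angle_gradient(cb, 0, 1, 2)
        hess += spec.k_bend * np.outer(g, g)
    elif spec.topology.startswith("chain-"):
        coords = np.array([[0.0, 0.0, i * b] for i in range(n)])
        cb = coords * units.BOHR_PER_ANGSTROM
        axis = np.array([0.0, 0.0, 1.0])
        for i in range(n - 1):
            _bond_block(hess, i, i + 1, spec.k_bond, cb)
        for i in range(n - 2):
            _perp_bend_blocks(hess, i, i + 1, i + 2, spec.k_bend, axis)
        linear = True
    elif spec.topology.startswith("cluster-"):
        rng = np.random.default_rng(spec.seed)
        # seeded random 3D cluster with all-pair springs: generically a
        # nonlinear molecule whose Hessian has full internal rank 3N-6
        coords = b * rng.normal(size=(n, 3)) * n ** (1.0 / 3.0)
        cb = coords * units.BOHR_PER_ANGSTROM
        for i in range(n):
            for j in range(i + 1, n):
                _bond_block(hess, i, j, spec.k_bond / n, cb)
    else:
        raise ValueError(f"unsupported topology: {spec.topology!r}")

    truth["linear"] = linear
    truth["n_internal_modes"] = 3 * n - 5 if linear else 3 * n - 6

    dip_der = np.zeros((n, 3, 3))
    for i in range(n):
        dip_der[i] = charges[i] * np.eye(3)
    symbols = ["X"] * n
    mol = Molecule(symbols, coords, masses=masses, charges=charges,
                   dipole_derivatives=dip_der,
                   metadata={"seed": spec.seed, "topology": spec.topology})
    return mol, HessianData(hess, mol), truth


# ---------------------------------------------------------------------------
# two-state environments
# ---------------------------------------------------------------------------

def make_two_state_environment(geometry: Molecule, donor_site, acceptor_site,
                               q_transfer: float = 1.0,
                               baseline: Optional[MultipoleEnvironment] = None,
                               min_separation: float = 1e-6,
                               ) -> tuple[MultipoleEnvironment, MultipoleEnvironment]:
    """Point-charge environments for the receptor before/after an electron
    transfer from the donor site to the acceptor site.

    State D (before) carries the baseline charges (neutral donor/acceptor
    sites by default); state A (after) adds +q_transfer at the donor site
    and -q_transfer at the acceptor site.  Sites must be distinct and must
    not coincide with any odorant atom.
    """
    donor_site = np.asarray(donor_site, dtype=float)
    acceptor_site = np.asarray(acceptor_site, dtype=float)
    if np.linalg.norm(donor_site - acceptor_site) < min_separation:
        raise ValueError("donor and acceptor sites coincide")
    for name, site in (("donor", donor_site), ("acceptor", acceptor_site)):
        d = np.linalg.norm(geometry.coords - site, axis=1).min()
        if d < min_separation:
            raise ValueError(f"{name} site coincides with an odorant atom "
                             f"(distance {d:.2e} A)")
    positions = np.vstack([donor_site, acceptor_site])
    base_q = np.zeros(2)
    if baseline is not None:
        positions = np.vstack([positions, baseline.positions])
        base_q = np.concatenate([base_q, baseline.charges])
    q_after = base_q.copy()
    q_after[0] += q_transfer
    q_after[1] -= q_transfer
    env_d = MultipoleEnvironment(positions.copy(), base_q, state="donor")
    env_a = MultipoleEnvironment(positions.copy(), q_after, state="acceptor")
    return env_d, env_a


# ---------------------------------------------------------------------------
# energy traces
# ---------------------------------------------------------------------------

def make_energy_traces(mean_donor: float, mean_acceptor: float,
                       width_donor: float, width_acceptor: float,
                       n: int = 100_000, seed: int = 0,
                       dt: float = 0.001) -> tuple[EnergyTrace, EnergyTrace]:
    """Independent Gaussian potential-energy traces for the two redox
    states; ``width`` follows the density convention SD = width/2.  The
    generating parameters are embedded in each trace's metadata."""
    if width_donor <= 0 or width_acceptor <= 0:
        raise ValueError("widths must be positive")
    rng = np.random.default_rng(seed)
    times = dt * (1 + np.arange(n))
    traces = []
    for state, mean, width in (("donor", mean_donor, width_donor),
                               ("acceptor", mean_acceptor, width_acceptor)):
        e = rng.normal(mean, width / 2.0, size=n)
        traces.append(EnergyTrace(times, e, state=state, metadata={
            "mean": mean, "width": width, "seed": seed, "n": n}))
    return traces[0], traces[1]


def make_traces_for_lambda(lambda_true: float, temperature: float = 310.0,
                           mean: float = -10_000.0, n: int = 100_000,
                           seed: int = 0) -> tuple[EnergyTrace, EnergyTrace]:
    """Two-state traces whose widths encode a chosen reorganization energy
    through the linear-response identity variance = 2 lambda R T (so
    width = sqrt(8 lambda R T)); means equal, mimicking the
    near-indistinguishable regime."""
    from .marcus_reorg import GAS_CONSTANT

    width = math.sqrt(8.0 * lambda_true * GAS_CONSTANT * temperature)
    d, a = make_energy_traces(mean, mean, width, width, n=n, seed=seed)
    for t in (d, a):
        t.metadata["lambda_true"] = lambda_true
        t.metadata["temperature"] = temperature
    return d, a


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_trajectory(base: Molecule, motion: str = "static",
                    n_frames: int = 100, seed: int = 0, dt: float = 0.001,
                    velocity=(0.1, 0.0, 0.0), amplitude: float = 0.3,
                    period: int = 20, step_sd: float = 0.05) -> Trajectory:
    """Scripted trajectories with closed-form expected series in metadata.

    motions:
      - ``static``: identical frames (expected RMSD identically zero);
      - ``drift``: rigid translation by ``velocity`` (A/frame); expected
        RMSD = |v| * frame;
      - ``oscillate``: atom 0 oscillates along the 0-1 axis with the given
        amplitude (A) and period (frames); expected 0-1 distance series
        d0 + A sin(2 pi f / period);
      - ``random_walk``: cumulative seeded Gaussian steps (SD ``step_sd``
        A/frame) for every atom.
    """
    base_xyz = base.coords
    frames = np.repeat(base_xyz[None], n_frames, axis=0).astype(float)
    meta: dict = {"motion": motion, "seed": seed}
    t = np.arange(n_frames)
    if motion == "static":
        meta["expected_rmsd"] = np.zeros(n_frames)
    elif motion == "drift":
        v = np.asarray(velocity, dtype=float)
        frames += t[:, None, None] * v[None, None, :]
        meta["expected_rmsd"] = t * np.linalg.norm(v)
    elif motion == "oscillate":
        if base.n_atoms < 2:
            raise ValueError("oscillate needs at least two atoms")
        axis = base_xyz[0] - base_xyz[1]
        d0 = np.linalg.norm(axis)
        axis = axis / d0
        disp = amplitude * np.sin(2.0 * math.pi * t / period)
        frames[:, 0, :] += disp[:, None] * axis[None, :]
        meta["expected_distance_01"] = d0 + disp
    elif motion == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, step_sd, size=(n_frames, base.n_atoms, 3))
        steps[0] = 0.0
        frames += np.cumsum(steps, axis=0)
    else:
        raise ValueError(f"unsupported motion: {motion!r}")
    return Trajectory(frames, dt * (1 + t), symbols=list(base.symbols),
                      metadata=meta)
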