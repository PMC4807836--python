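"""Trajectory metrics: rigid-body alignment, RMSD and distance series,
running averages, nonbonded interaction-energy decomposition and
normalized energy histograms.

Electrostatics uses the direct pairwise Coulomb sum with the MD constant
332.0636 kcal A / (mol e^2) and a hard cutoff; van der Waals uses the
12-6 Lennard-Jones form with a CHARMM-style energy switching function
between the switch-on distance and the cutoff, so the vdW energy goes
smoothly (C^1) to zero at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .molecular_io import read_xyz_frames
from .units import COULOMB_KCAL_A_E2


@dataclass
class Trajectory:
    """Frames of coordinates (n_frames, N, 3) Angstrom at times (ns) for a
    fixed atom list, with optional named index selections."""

    coords: np.ndarray
    times: np.ndarray
    symbols: Optional[list[str]] = None
    selections: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, N, 3)")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.coords):
            raise ValueError("one time stamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, name_or_indices) -> np.ndarray:
        if isinstance(name_or_indices, str):
            idx = np.asarray(self.selections[name_or_indices], dtype=int)
        else:
            idx = np.asarray(name_or_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise IndexError(f"selection index out of range 0..{self.n_atoms - 1}")
        return idx


def load_trajectory(path: str | Path, dt: float = 1.0,
                    format: Optional[str] = None) -> Trajectory:
    """Load a multi-frame XYZ (native) or DCD (via MDAnalysis, which then
    needs a companion topology readable by MDAnalysis) trajectory;
    ``dt`` is the frame spacing in ns."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        frames = read_xyz_frames(path)
        coords = np.array([f.coords for f in frames])
        times = dt * np.arange(len(frames))
        return Trajectory(coords, times, symbols=frames[0].symbols)
    if fmt == "dcd":
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        return Trajectory(coords, dt * np.arange(len(coords)))
    raise ValueError(f"unsupported trajectory format: {fmt!r}")


@dataclass
class NonbondedParams:
    """Per-atom charges (e), LJ well depths epsilon (kcal/mol) and pair
    minimum distances r_min (Angstrom, arithmetic-mean combined), plus the
    switching window."""

    charges: np.ndarray
    epsilons: np.ndarray
    r_mins: np.ndarray
    cutoff: float = 12.0
    switch_on: float = 10.0

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.r_mins = np.asarray(self.r_mins, dtype=float)
        if np.any(self.epsilons < 0):
            raise ValueError("epsilon must be non-negative")
        if np.any(self.r_mins <= 0):
            raise ValueError("r_min must be positive")
        if not self.switch_on < self.cutoff:
            raise ValueError("switch-on distance must be below the cutoff")

    def check_covers(self, indices: np.ndarray) -> None:
        n = len(self.charges)
        bad = [int(i) for i in indices if i >= n]
        if bad:
            raise ValueError(f"missing nonbonded parameters for atom(s) {bad}")


# ---------------------------------------------------------------------------
# alignment and geometric series
# ---------------------------------------------------------------------------

def _kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (applied as x @ R.T) minimizing |R.moving - target|
    for pre-centered coordinate sets."""
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def align_frames(traj: Trajectory, reference_selection) -> Trajectory:
    """Superpose every frame onto frame 0 by the least-squares rigid-body
    fit over ``reference_selection`` (a name or index list; >= 3 atoms)."""
    sel = traj.select(reference_selection)
    if sel.size < 3:
        raise ValueError("alignment needs at least 3 atoms (rotation is "
                         "underdetermined otherwise)")
    ref = traj.coords[0, sel]
    ref_cen = ref.mean(axis=0)
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mob = traj.coords[f, sel]
        cen = mob.mean(axis=0)
        rot = _kabsch_rotation(mob - cen, ref - ref_cen)
        out[f] = (traj.coords[f] - cen) @ rot.T + ref_cen
    return Trajectory(out, traj.times.copy(), symbols=traj.symbols,
                      selections=dict(traj.selections),
                      metadata={**traj.metadata, "aligned_on": list(map(int, sel))})


def rmsd_series(traj: Trajectory, selection, reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of a selection against a reference frame
    (no re-fitting: align first if rigid-body motion should be removed)."""
    sel = traj.select(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = traj.coords[reference_frame, sel]
    diff = traj.coords[:, sel] - ref
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def distance_series(traj: Trajectory, atom_a: int, atom_b: int) -> np.ndarray:
    """Euclidean distance (Angstrom) between two atoms per frame."""
    for i in (atom_a, atom_b):
        if not 0 <= i < traj.n_atoms:
            raise IndexError(f"atom index {i} out of range 0..{traj.n_atoms - 1}")
    return np.linalg.norm(traj.coords[:, atom_a] - traj.coords[:, atom_b], axis=1)


def running_mean(series: np.ndarray, window: int = 50) -> np.ndarray:
    """Centered moving average with a window that shrinks symmetrically at
    the edges (window = 1 is the identity)."""
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    half = (window - 1) // 2
    out = np.empty_like(series)
    for i in range(len(series)):
        k = min(i, len(series) - 1 - i, half)
        out[i] = series[i - k : i + k + 1].mean()
    return out


# ---------------------------------------------------------------------------
# nonbonded interaction energies
# ---------------------------------------------------------------------------

def _switch_factor(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM energy-switching function: 1 below r_on, 0 beyond r_off,
    C^1 polynomial blend in between."""
    s = np.ones_like(r)
    s[r >= r_off] = 0.0
    mid = (r > r_on) & (r < r_off)
    r2, on2, off2 = r[mid] ** 2, r_on**2, r_off**2
    s[mid] = ((off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2)
              / (off2 - on2) ** 3)
    return s


def interaction_energy(traj: Trajectory, group_a, group_b,
                       params: NonbondedParams) -> dict[str, np.ndarray]:
    """Electrostatic, van der Waals and total interaction-energy series
    (kcal/mol) between two disjoint atom groups.

    Coulomb: q_i q_j * 332.0636 / r_ij, truncated at the cutoff.
    vdW: eps_ij [ (rmin_ij/r)^12 - 2 (rmin_ij/r)^6 ] with energy switching
    between ``switch_on`` and ``cutoff``.
    """
    a = traj.select(group_a)
    b = traj.select(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap; interaction energy needs disjoint "
                         "selections")
    params.check_covers(np.concatenate([a, b]))

    qq = COULOMB_KCAL_A_E2 * np.outer(params.charges[a], params.charges[b])
    eps = np.sqrt(np.outer(params.epsilons[a], params.epsilons[b]))
    rmin = 0.5 * (params.r_mins[a][:, None] + params.r_mins[b][None, :])

    elec = np.empty(traj.n_frames)
    vdw = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = traj.coords[f, a][:, None, :] - traj.coords[f, b][None, :, :]
        r = np.linalg.norm(d, axis=2)
        inside = r < params.cutoff
        elec[f] = (qq[inside] / r[inside]).sum()
        x6 = (rmin / r) ** 6
        lj = eps * (x6**2 - 2.0 * x6)
        sw = _switch_factor(r, params.switch_on, params.cutoff)
        vdw[f] = (lj * sw)[inside].sum()
    return {"electrostatic": elec, "vdw": vdw, "total": elec + vdw}


def energy_distribution(series: np.ndarray, bins: int = 50):
    """Density-normalized histogram of an energy series; returns
    (densities, bin_edges); the densities integrate to one."""
    series = np.asarray(series, dtype=float)
    if np.unique(series).size < 2:
        raise ValueError("degenerate series: need at least 2 distinct values")
    return np.histogram(series, bins=bins, density=True)
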