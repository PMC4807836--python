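"""Readers and writers for geometries, Hessians, embedding potentials,
trajectories and potential-energy traces.

All file formats are plain text.  Geometries are exchanged in Angstrom,
Hessians in Hartree/Bohr^2 (converted on load when supplied in
kcal/mol/A^2), multipole environments in Angstrom + atomic units, energy
traces in ns + kcal/mol.  Atom indices are 0-based internally; native
1-based serial numbers are kept only inside the files themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import units

logger = logging.getLogger(__name__)

#: standard atomic weights (amu), sufficient for organic/bio systems
ATOMIC_MASSES = {
    "H": 1.00794, "D": 2.014102, "He": 4.002602,
    "Li": 6.941, "Be": 9.012182, "B": 10.811, "C": 12.0107,
    "N": 14.0067, "O": 15.9994, "F": 18.9984032, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.3050, "Al": 26.9815386, "Si": 28.0855,
    "P": 30.973762, "S": 32.065, "Cl": 35.453, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38,
    "Se": 78.96, "Br": 79.904, "I": 126.90447,
    # single-letter placeholders for toy models
    "X": 1.0,
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def mass_of(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol.capitalize() if len(symbol) > 1 else symbol.upper()]
    except KeyError:
        raise ParseError(f"unknown element symbol: {symbol!r}") from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Molecule:
    """A molecule: symbols, masses (amu), Cartesian coordinates (Angstrom),
    optional per-atom partial charges (e) and dipole-derivative tensors
    d(mu)/d(r) in atomic units, shape (N, 3, 3) indexed [atom, dipole
    component, displacement component]."""

    symbols: list[str]
    coords: np.ndarray  # (N, 3), Angstrom
    masses: Optional[np.ndarray] = None  # (N,), amu
    charges: Optional[np.ndarray] = None  # (N,), e
    dipole_derivatives: Optional[np.ndarray] = None  # (N, 3, 3), au
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.masses is None:
            self.masses = np.array([mass_of(s) for s in self.symbols], dtype=float)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if len(self.symbols) != len(self.coords) or len(self.masses) != len(self.coords):
            raise ValueError("symbols, coords and masses must have the same length")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (self.n_atoms,):
                raise ValueError("charges must have one entry per atom")
        if self.dipole_derivatives is not None:
            self.dipole_derivatives = np.asarray(self.dipole_derivatives, dtype=float)
            if self.dipole_derivatives.shape != (self.n_atoms, 3, 3):
                raise ValueError("dipole derivatives must have shape (N, 3, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()


@dataclass
class HessianData:
    """Cartesian Hessian in Hartree/Bohr^2, symmetrized, with the molecule it
    refers to."""

    matrix: np.ndarray  # (3N, 3N), au
    molecule: Molecule

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = 3 * self.molecule.n_atoms
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"Hessian dimension {self.matrix.shape} does not match 3N = {n}"
            )
        asym = np.abs(self.matrix - self.matrix.T).max()
        if asym > 1e-4:
            logger.warning("Hessian asymmetry %.3e au exceeds 1e-4; symmetrizing", asym)
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class EnergyTrace:
    """Potential-energy time series for one redox state: times (ns),
    energies (kcal/mol), state label in {'donor', 'acceptor'} or free-form."""

    times: np.ndarray
    energies: np.ndarray
    state: str = "donor"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.size < 2:
            raise ValueError("an energy trace needs at least 2 samples")
        if self.times.shape != self.energies.shape:
            raise ValueError("times and energies must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# geometry I/O
# ---------------------------------------------------------------------------

def read_geometry(path: str | Path, format: Optional[str] = None) -> Molecule:
    """Read a single geometry from an XYZ or PDB file.

    The format is inferred from the suffix when not given.  Charges are
    never read from geometry files; attach them separately.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        frames = read_xyz_frames(path)
        return frames[0]
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unsupported geometry format: {fmt!r}")


def read_xyz_frames(path: str | Path) -> list[Molecule]:
    """Read all frames of a (multi-frame) XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames: list[Molecule] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got "
                             f"{lines[i]!r}") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame starting at line {i + 1}")
        symbols, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i + 3 + j}: malformed atom record "
                                 f"{ln!r}")
            symbols.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ParseError(f"{path}: line {i + 3 + j}: non-numeric coordinate "
                                 f"in {ln!r}") from None
        frames.append(Molecule(symbols, np.array(coords),
                               metadata={"comment": comment.strip()}))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_xyz(path: str | Path, molecules: Molecule | Sequence[Molecule],
              comment: str = "") -> None:
    """Write one molecule or a sequence of frames to an XYZ file."""
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.n_atoms}\n{comment or mol.metadata.get('comment', '')}\n")
            for s, (x, y, z) in zip(mol.symbols, mol.coords):
                fh.write(f"{s:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _read_pdb(path: Path) -> Molecule:
    """Coordinates-only PDB reader (biotite when available, otherwise the
    fixed-column ATOM/HETATM records directly); no topology inference."""
    try:
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
        symbols = [e.capitalize() for e in arr.element]
        return Molecule(symbols, np.asarray(arr.coord, dtype=float))
    except ImportError:  # pragma: no cover - biotite is normally present
        symbols, coords = [], []
        for ln in Path(path).read_text().splitlines():
            if ln.startswith(("ATOM", "HETATM")):
                symbols.append(ln[76:78].strip().capitalize() or ln[12:16].strip()[0])
                coords.append([float(ln[30:38]), float(ln[38:46]), float(ln[46:54])])
        if not symbols:
            raise ParseError(f"{path}: no ATOM/HETATM records")
        return Molecule(symbols, np.array(coords))


# ---------------------------------------------------------------------------
# Hessian I/O
# ---------------------------------------------------------------------------

def read_hessian(path: str | Path, molecule: Molecule,
                 units_in: str = "au") -> HessianData:
    """Read a whitespace-separated 3N x 3N Hessian (full matrix, or the lower
    triangle row by row) and return it in atomic units, symmetrized.

    ``units_in`` is ``'au'`` (Hartree/Bohr^2) or ``'kcal_mol_A2'``.
    """
    values = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#")[0].strip()
        if ln:
            values.extend(float(x) for x in ln.split())
    n = 3 * molecule.n_atoms
    full, tri = n * n, n * (n + 1) // 2
    if len(values) == full:
        mat = np.array(values).reshape(n, n)
    elif len(values) == tri:
        mat = np.zeros((n, n))
        mat[np.tril_indices(n)] = values
        mat = mat + mat.T - np.diag(np.diag(mat))
    else:
        raise ParseError(
            f"{path}: expected {full} (full) or {tri} (lower-triangular) values "
            f"for {molecule.n_atoms} atoms, found {len(values)}"
        )
    if units_in == "kcal_mol_A2":
        mat = mat * units.HARTREE_PER_KCALMOL / units.BOHR_PER_ANGSTROM**2
    elif units_in != "au":
        raise ValueError(f"unknown Hessian units: {units_in!r}")
    return HessianData(mat, molecule)


def write_hessian(path: str | Path, hessian: HessianData) -> None:
    np.savetxt(path, hessian.matrix, fmt="%22.14e")


# ---------------------------------------------------------------------------
# embedding potential I/O
# ---------------------------------------------------------------------------

def read_potential(path: str | Path, state: str = "donor"):
    """Read a distributed-multipole embedding potential.

    One site per line::

        index  x y z  q  [dx dy dz]  [qxx qxy qxz qyy qyz qzz]
                           [axx axy axz ayy ayz azz]

    positions in Angstrom, moments/polarizabilities in atomic units; missing
    trailing groups default to zero.  Returns a
    :class:`~vibro.embedding_field.MultipoleEnvironment`.
    """
    from .embedding_field import MultipoleEnvironment

    positions, charges, dipoles, quads, polars = [], [], [], [], []
    seen: set[int] = set()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.split()
        try:
            idx = int(parts[0])
            nums = [float(x) for x in parts[1:]]
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric field in {ln!r}") \
                from None
        if idx in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate site index {idx}")
        seen.add(idx)
        if len(nums) not in (4, 7, 13, 19):
            raise ParseError(f"{path}: line {lineno}: expected 4, 7, 13 or 19 "
                             f"numeric fields, found {len(nums)}")
        positions.append(nums[0:3])
        charges.append(nums[3])
        dipoles.append(nums[4:7] if len(nums) >= 7 else [0.0] * 3)
        quads.append(_unpack_sym(nums[7:13]) if len(nums) >= 13 else np.zeros((3, 3)))
        polars.append(_unpack_sym(nums[13:19]) if len(nums) >= 19 else np.zeros((3, 3)))
    if not positions:
        raise ParseError(f"{path}: no sites found")
    return MultipoleEnvironment(
        positions=np.array(positions), charges=np.array(charges),
        dipoles=np.array(dipoles), quadrupoles=np.array(quads),
        polarizabilities=np.array(polars), state=state,
    )


def _unpack_sym(six: Sequence[float]) -> np.ndarray:
    xx, xy, xz, yy, yz, zz = six
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def write_potential(path: str | Path, env) -> None:
    """Write a MultipoleEnvironment in the format of :func:`read_potential`,
    emitting only the trailing groups that are nonzero for any site."""
    has_d = np.any(env.dipoles != 0)
    has_q = np.any(env.quadrupoles != 0) or np.any(env.polarizabilities != 0)
    has_a = np.any(env.polarizabilities != 0)
    with open(path, "w") as fh:
        fh.write("# index x y z q [dx dy dz] [qxx qxy qxz qyy qyz qzz] "
                 "[axx axy axz ayy ayz azz]\n")
        for i in range(env.n_sites):
            fields = list(env.positions[i]) + [env.charges[i]]
            if has_d or has_q:
                fields += list(env.dipoles[i])
            if has_q:
                fields += _pack_sym(env.quadrupoles[i])
            if has_a:
                fields += _pack_sym(env.polarizabilities[i])
            fh.write(f"{i + 1:d} " + " ".join(f"{v:.16e}" for v in fields) + "\n")


def _pack_sym(m: np.ndarray) -> list[float]:
    return [m[0, 0], m[0, 1], m[0, 2], m[1, 1], m[1, 2], m[2, 2]]


# ---------------------------------------------------------------------------
# energy traces
# ---------------------------------------------------------------------------

def read_energy_trace(path: str | Path, state: str = "donor") -> EnergyTrace:
    """Read a two-column TSV (time [ns], energy [kcal/mol]); '#' comments."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["time", "energy"])
    if df.empty:
        raise ParseError(f"{path}: no samples")
    return EnergyTrace(df["time"].to_numpy(), df["energy"].to_numpy(), state=state)


def write_energy_trace(path: str | Path, trace: EnergyTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# state: {trace.state}\n# time_ns\tenergy_kcal_mol\n")
        for t, e in zip(trace.times, trace.energies):
            fh.write(f"{t:.9g}\t{e:.10g}\n")
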