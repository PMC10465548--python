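"""Molecular structure and sequence I/O.

Reads PQR files (PDB2PQR dialect: ATOM/HETATM records with per-atom
partial charge and radius), builds :class:`RigidMolecule` objects carrying
everything the pair energy model needs (coordinates, charges,
Lennard-Jones parameters, residue labels), and handles aligned multi-FASTA
sequence input for the substitution analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO, Align
from Bio.Align import substitution_matrices

__all__ = [
    "AtomRecord",
    "RigidMolecule",
    "Sequence",
    "read_pqr",
    "write_pqr",
    "molecule_mass",
    "read_alignment",
    "percent_identity",
]

# AMBER-ff99-style Lennard-Jones parameters by element: (epsilon kcal/mol,
# Rmin/2 in Å).  Values are the common AMBER atom-type values collapsed to
# the dominant type per element (CT, N, O/OH, SH, HC, P).  Specific
# (residue_name, atom_name) overrides take precedence when present.
_LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "C": (0.1094, 1.9080),
    "N": (0.1700, 1.8240),
    "O": (0.2100, 1.6612),
    "S": (0.2500, 2.0000),
    "H": (0.0157, 0.6000),
    "P": (0.2000, 2.1000),
}

# (residue_name, atom_name) -> (epsilon, Rmin/2) overrides; extended as needed.
_LJ_OVERRIDES: dict[tuple[str, str], tuple[float, float]] = {}

_ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
}

_TWO_CHAR_ELEMENTS = {"SE", "FE", "ZN", "MG", "NA", "CL", "BR", "MN", "CU"}

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY-X")

# 2^(1/6): converts an Rmin (potential-minimum) distance to the LJ sigma
# (zero-crossing) distance.
_RMIN_TO_SIGMA = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with everything the pair energy model needs.

    ``lj_sigma`` is the self-pair zero-crossing distance sigma_ii; the
    hard-core radius of the atom is ``core_radius = lj_sigma / 2``.
    """

    serial: int
    name: str
    residue_name: str
    residue_index: int
    chain: str
    position: np.ndarray  # (3,) Å
    charge: float  # e
    lj_epsilon: float  # kcal/mol
    lj_sigma: float  # Å

    @property
    def core_radius(self) -> float:
        return self.lj_sigma / 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial} ({self.name}): lj_epsilon < 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"atom {self.serial} ({self.name}): lj_sigma must be > 0")


@dataclass
class RigidMolecule:
    """A rigid collection of atoms, the unit of all energetics.

    Coordinates are stored as given; :meth:`centered` returns a copy whose
    geometric center sits at the origin, which is the convention used by
    the FFT scan and the pose bookkeeping.
    """

    label: str
    atoms: list[AtomRecord]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    @property
    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms])

    @property
    def core_radii(self) -> np.ndarray:
        return self.lj_sigmas / 2.0

    @property
    def residues(self) -> list[tuple[str, int]]:
        """Ordered (name, index) residue list, in order of first appearance."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, a.residue_name)
        return [(name, idx) for idx, name in seen.items()]

    def residue_atom_indices(self) -> dict[int, np.ndarray]:
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_index, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def centered(self) -> "RigidMolecule":
        c = self.center
        atoms = [replace(a, position=a.position - c) for a in self.atoms]
        return RigidMolecule(self.label, atoms)

    def radius(self) -> float:
        """Largest atom-center distance from the geometric center plus that
        atom's hard-core radius (a bounding-sphere radius)."""
        d = np.linalg.norm(self.coords - self.center, axis=1)
        return float(np.max(d + self.core_radii))


@dataclass(frozen=True)
class Sequence:
    """A one-letter amino-acid sequence, possibly gapped."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id}: unexpected characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def infer_element(atom_name: str) -> str:
    """Element symbol from a PDB/PQR atom name.

    Names starting with a digit (e.g. ``1HB``) are hydrogens; two-character
    elements are recognised from a fixed list, otherwise the first letter wins.
    """
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in _TWO_CHAR_ELEMENTS:
        return two
    return stripped[0].upper()


def lj_parameters(
    residue_name: str, atom_name: str, sigma_convention: str = "rmin"
) -> tuple[float, float]:
    """(epsilon, sigma_ii) for an atom, from the bundled AMBER-style table.

    ``sigma_convention`` controls whether the tabulated radius is an
    Rmin/2 value (AMBER convention; sigma = 2*(Rmin/2)/2^(1/6)) or already
    a sigma/2 value.  Unknown atoms raise, never default silently.
    """
    key = (residue_name.strip().upper(), atom_name.strip().upper())
    if key in _LJ_OVERRIDES:
        eps, r2 = _LJ_OVERRIDES[key]
    else:
        element = infer_element(atom_name)
        if element not in _LJ_BY_ELEMENT:
            raise KeyError(
                f"no Lennard-Jones parameters for atom {atom_name!r} in residue "
                f"{residue_name!r} (element {element!r} not in the bundled table)"
            )
        eps, r2 = _LJ_BY_ELEMENT[element]
    if sigma_convention == "rmin":
        sigma = 2.0 * r2 / _RMIN_TO_SIGMA
    elif sigma_convention == "sigma":
        sigma = 2.0 * r2
    else:
        raise ValueError(f"sigma_convention must be 'rmin' or 'sigma', got {sigma_convention!r}")
    return eps, sigma


def read_pqr(path: str | Path, sigma_convention: str = "rmin") -> RigidMolecule:
    """Parse a PQR file into a :class:`RigidMolecule`.

    PQR is whitespace-delimited (PDB2PQR output is not fixed-width):
    ``ATOM serial name resName [chain] resSeq x y z charge radius``.
    Charges and radii come from the file: the radius column defines the
    atom's hard core (sigma_ii = 2*radius/2^(1/6) under the default
    ``rmin`` convention, sigma_ii = 2*radius under ``sigma``).  The
    bundled AMBER-style table supplies lj_epsilon, and both epsilon and
    sigma whenever the file's radius is zero (some polar hydrogens).
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            fields = line.split()
            # chain id is optional in PQR; detect by field count
            if len(fields) == 11:
                _, serial, name, resname, chain, resseq, x, y, z, q, _r = fields
            elif len(fields) == 10:
                _, serial, name, resname, resseq, x, y, z, q, _r = fields
                chain = ""
            else:
                raise ValueError(f"{path}:{lineno}: malformed PQR record ({len(fields)} fields)")
            try:
                pos = np.array([float(x), float(y), float(z)])
                charge = float(q)
                radius = float(_r)
                serial_i = int(serial)
                resseq_i = int("".join(c for c in resseq if c.isdigit() or c == "-"))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            eps, table_sigma = lj_parameters(resname, name, sigma_convention)
            if radius > 0:
                sigma = 2.0 * radius / _RMIN_TO_SIGMA if sigma_convention == "rmin" else 2.0 * radius
            else:
                sigma = table_sigma
            atoms.append(
                AtomRecord(
                    serial=serial_i,
                    name=name,
                    residue_name=resname,
                    residue_index=resseq_i,
                    chain=chain,
                    position=pos,
                    charge=charge,
                    lj_epsilon=eps,
                    lj_sigma=sigma,
                )
            )
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return RigidMolecule(label=path.stem, atoms=atoms)


def write_pqr(mol: RigidMolecule, path: str | Path) -> None:
    """Write a PQR file (whitespace-delimited, PDB2PQR style).

    The radius column holds the hard-core radius sigma_ii/2 so that a
    round-trip through :func:`read_pqr` with ``sigma_convention='sigma'``
    reproduces the molecule's steric model exactly.
    """
    with open(path, "w") as fh:
        for a in mol.atoms:
            chain = a.chain if a.chain else "A"
            fh.write(
                f"ATOM  {a.serial:>5d} {a.name:<4s} {a.residue_name:<4s}{chain:1s} "
                f"{a.residue_index:>4d}    "
                f"{a.position[0]:8.3f} {a.position[1]:8.3f} {a.position[2]:8.3f} "
                f"{a.charge:8.4f} {a.core_radius:7.4f}\n"
            )
        fh.write("END\n")


def molecule_mass(mol: RigidMolecule) -> float:
    """Molecular mass in Da, from per-atom elements inferred from names."""
    total = 0.0
    for a in mol.atoms:
        element = infer_element(a.name)
        if element not in _ATOMIC_MASS:
            raise KeyError(f"no atomic mass for element {element!r} (atom {a.name!r})")
        total += _ATOMIC_MASS[element]
    return total


def read_alignment(path: str | Path) -> list[Sequence]:
    """Read an aligned multi-FASTA; all sequences must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    seqs = [Sequence(id=r.id, residues=str(r.seq).upper()) for r in records]
    ref_len = len(seqs[0])
    for s in seqs:
        if len(s) != ref_len:
            raise ValueError(
                f"alignment length mismatch: {s.id} has {len(s)} columns, "
                f"{seqs[0].id} has {ref_len}"
            )
    return seqs


def _align_pair(a: Sequence, b: Sequence) -> tuple[str, str]:
    """Global Needleman-Wunsch alignment with BLOSUM62, gap open 10 / extend 0.5."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.residues, b.residues)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def percent_identity(a: Sequence, b: Sequence) -> float:
    """Percent sequence identity between two sequences.

    If the inputs have equal length they are taken as already aligned;
    otherwise a global alignment is performed first.  The denominator is
    the number of columns where both sequences carry a residue (gap
    columns excluded), matching the conventional ClustalW report.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("percent_identity: empty sequence")
    if len(a) == len(b):
        sa, sb = a.residues, b.residues
    else:
        sa, sb = _align_pair(a, b)
    both = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not both:
        raise ValueError("percent_identity: no aligned residue pairs")
    ident = sum(1 for x, y in both if x == y)
    return 100.0 * ident / len(both)
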