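"""Deterministic toy molecules for end-to-end testing without downloads.

Three kinds: a single Lennard-Jones sphere, a charged dumbbell (two
atoms, opposite charges, two residues — the smallest molecule with a
dipole and a decomposable residue structure), and a tetra-atom
"mini-protein" (four atoms in two residues).  All are valid
:class:`RigidMolecule` instances and can be written as PQR files that
round-trip through the structure reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AtomRecord, RigidMolecule, write_pqr

__all__ = ["ToySpec", "make_toy"]

_KINDS = ("sphere", "charged_dumbbell", "tetramer")


@dataclass(frozen=True)
class ToySpec:
    """Parameters of a toy rigid molecule.

    ``lj_sigma`` is the self-pair sigma_ii of every atom (hard-core
    diameter for the homotypic contact); ``charge`` is the magnitude used
    by the charged kinds; ``separation`` the bond length in Å.
    """

    kind: str
    lj_sigma: float = 4.0
    lj_epsilon: float = 0.2
    charge: float = 0.0
    separation: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.lj_sigma <= 0 or self.lj_epsilon < 0 or self.separation <= 0:
            raise ValueError("lj_sigma and separation must be > 0, lj_epsilon >= 0")


def _atom(serial, name, resname, resindex, pos, charge, eps, sigma) -> AtomRecord:
    return AtomRecord(
        serial=serial, name=name, residue_name=resname, residue_index=resindex,
        chain="A", position=np.asarray(pos, dtype=float), charge=charge,
        lj_epsilon=eps, lj_sigma=sigma,
    )


def make_toy(spec: ToySpec, pqr_path: str | Path | None = None) -> RigidMolecule:
    """Build a toy molecule; optionally also write it as a PQR file."""
    s, e = spec.lj_sigma, spec.lj_epsilon
    d = spec.separation
    if spec.kind == "sphere":
        atoms = [_atom(1, "C", "SPH", 1, [0.0, 0.0, 0.0], spec.charge, e, s)]
        label = "toy_sphere"
    elif spec.kind == "charged_dumbbell":
        q = spec.charge if spec.charge != 0.0 else 1.0
        atoms = [
            _atom(1, "C", "DBA", 1, [-d / 2.0, 0.0, 0.0], +q, e, s),
            _atom(2, "C", "DBB", 2, [+d / 2.0, 0.0, 0.0], -q, e, s),
        ]
        label = "toy_dumbbell"
    else:  # tetramer: two residues of two atoms, a flat rhombus
        q = spec.charge
        h = d / 2.0
        atoms = [
            _atom(1, "C", "TTA", 1, [-h, 0.0, 0.0], +q, e, s),
            _atom(2, "C", "TTA", 1, [0.0, +h, 0.0], -q, e, s),
            _atom(3, "C", "TTB", 2, [+h, 0.0, 0.0], +q, e, s),
            _atom(4, "C", "TTB", 2, [0.0, -h, 0.0], -q, e, s),
        ]
        label = "toy_tetramer"
    mol = RigidMolecule(label=label, atoms=atoms)
    if pqr_path is not None:
        write_pqr(mol, pqr_path)
    return mol
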