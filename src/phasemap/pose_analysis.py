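"""Analysis of low-energy pair poses.

Poses saved by the insertion scans (test-molecule placements with
energies below the archive threshold) are ranked, clustered by
ligand-RMSD — the RMSD between two placements of the test molecule with
the central copy held fixed — and decomposed into per-residue energy
profiles whose differences between two proteins flag the positions that
drive changes in interaction strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .energy_model import EnergyParams, KB, molecule_pair_energy, residue_decompose, transform_coords
from .structure_io import RigidMolecule

__all__ = [
    "PoseRecord",
    "PoseCluster",
    "ResidueProfile",
    "select_lowest",
    "ligand_rmsd",
    "cluster_poses",
    "residue_profile",
    "compare_profiles",
    "site_distance_distribution",
    "large_cluster_fraction",
]

LARGE_CLUSTER_SIZE = 20

_BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3"}


@dataclass(frozen=True)
class PoseRecord:
    """One saved test-molecule placement relative to the central copy."""

    position: np.ndarray  # (3,) Å, test-molecule center
    orientation: np.ndarray  # quaternion [x,y,z,w]
    energy: float  # kcal/mol
    source: str  # "fmapb2" | "widom"
    config_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))

    def pose(self):
        return (self.position, self.orientation)

    def sort_key(self):
        return (self.energy, tuple(np.round(self.position, 9)), tuple(np.round(self.orientation, 9)))


@dataclass
class PoseCluster:
    """Poses within the ligand-RMSD cutoff of the defining (lowest-energy) member."""

    members: list  # PoseRecord
    representative: PoseRecord

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_large(self) -> bool:
        return self.size >= LARGE_CLUSTER_SIZE


def select_lowest(poses, k: int = 1000) -> list:
    """The k lowest-energy poses, deterministic under ties.

    Returns all poses (in sorted order) when fewer than k are available.
    """
    ordered = sorted(poses, key=lambda p: p.sort_key())
    return ordered[:k]


def ligand_rmsd(a: PoseRecord, b: PoseRecord, mol: RigidMolecule) -> float:
    """RMSD between two placements of the test molecule (central frame fixed)."""
    mol_c = mol.centered()
    ca = transform_coords(mol_c, a.pose())
    cb = transform_coords(mol_c, b.pose())
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def cluster_poses(poses, mol: RigidMolecule, cutoff: float = 10.0) -> list:
    """Greedy energy-ordered clustering by ligand-RMSD.

    The lowest-energy unassigned pose seeds a cluster and absorbs every
    unassigned pose within the cutoff of it; absorbed members are never
    re-assigned to later clusters.
    """
    remaining = select_lowest(poses, k=len(list(poses)) if not isinstance(poses, list) else len(poses))
    clusters: list[PoseCluster] = []
    assigned = np.zeros(len(remaining), dtype=bool)
    for i, seed in enumerate(remaining):
        if assigned[i]:
            continue
        members = [seed]
        assigned[i] = True
        for j in range(i + 1, len(remaining)):
            if assigned[j]:
                continue
            if ligand_rmsd(seed, remaining[j], mol) <= cutoff:
                members.append(remaining[j])
                assigned[j] = True
        clusters.append(PoseCluster(members=members, representative=seed))
    return clusters


def large_cluster_fraction(clusters) -> float:
    """Fraction of all poses collected by clusters of >= 20 members."""
    total = sum(c.size for c in clusters)
    if total == 0:
        return 0.0
    return sum(c.size for c in clusters if c.is_large) / total


@dataclass
class ResidueProfile:
    """Per-residue mean energy contribution over a pose set, in kcal/mol."""

    residue_indices: list
    residue_names: list
    means: np.ndarray
    n_poses: int

    def as_dict(self) -> dict:
        return dict(zip(self.residue_indices, self.means))


def residue_profile(
    poses,
    central: RigidMolecule,
    test: RigidMolecule,
    params: EnergyParams,
) -> ResidueProfile:
    """Two-way residue decomposition averaged over poses.

    For each pose, the pair energy is decomposed into contributions of
    the test molecule's residues against the whole central copy, and —
    since the two partners share a sequence when homotypic — the
    opposite way as well; results are averaged first over poses, then
    over the two decomposition directions.  Heterotypic pairs with
    differing residue lists are decomposed one way only (the test's).
    """
    poses = list(poses)
    if not poses:
        raise ValueError("no poses to profile")
    central_c = central.centered()
    test_c = test.centered()
    res_c = central_c.residues
    res_t = test_c.residues
    two_way = [name for name, _ in res_c] == [name for name, _ in res_t]
    acc_t: dict[int, float] = {idx: 0.0 for _, idx in res_t}
    acc_c: dict[int, float] = {idx: 0.0 for _, idx in res_c}
    for p in poses:
        dec_t = residue_decompose(central_c, test_c, p.pose(), params, decompose="B")
        for k, v in dec_t.items():
            acc_t[k] += v
        if two_way:
            dec_c = residue_decompose(central_c, test_c, p.pose(), params, decompose="A")
            for k, v in dec_c.items():
                acc_c[k] += v
    n = len(poses)
    if two_way:
        means = np.array([(acc_t[idx] + acc_c[idx]) / (2 * n) for _, idx in res_t])
    else:
        means = np.array([acc_t[idx] / n for _, idx in res_t])
    return ResidueProfile(
        residue_indices=[idx for _, idx in res_t],
        residue_names=[name for name, _ in res_t],
        means=means,
        n_poses=n,
    )


def compare_profiles(
    a: ResidueProfile,
    b: ResidueProfile,
    mapping: list | None = None,
    n_sd: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delta profile (a - b) with significance flags at mean +- n_sd*SD.

    ``mapping`` is a list of (index_in_a or None, index_in_b or None)
    pairs aligning the two sequences; positions aligned to a gap
    contribute 0.  Defaults to position-by-position when lengths match.
    Returns (positions, deltas, flags).
    """
    da, db = a.as_dict(), b.as_dict()
    if mapping is None:
        if len(a.residue_indices) != len(b.residue_indices):
            raise ValueError("profiles differ in length; provide an explicit mapping")
        mapping = list(zip(a.residue_indices, b.residue_indices))
    deltas = np.array([
        (da.get(ia, 0.0) if ia is not None else 0.0)
        - (db.get(ib, 0.0) if ib is not None else 0.0)
        for ia, ib in mapping
    ])
    mu, sd = deltas.mean(), deltas.std(ddof=0)
    flags = np.abs(deltas - mu) > n_sd * sd if sd > 0 else np.zeros(len(deltas), dtype=bool)
    positions = np.arange(1, len(mapping) + 1)
    return positions, deltas, flags


def _sidechain_centroid(mol: RigidMolecule, residue_index: int) -> np.ndarray:
    ids = mol.residue_atom_indices().get(residue_index)
    if ids is None:
        raise KeyError(f"residue index {residue_index} not in molecule {mol.label}")
    atoms = [mol.atoms[i] for i in ids]
    side = [a for a in atoms if a.name.strip().upper() not in _BACKBONE_NAMES]
    use = side if side else atoms
    return np.mean([a.position for a in use], axis=0)


def site_distance_distribution(
    poses,
    central: RigidMolecule,
    test: RigidMolecule,
    residue_index: int,
    bins: np.ndarray,
    weighting: str = "none",
    temperature: float = 298.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of distances between one residue's sidechain centroid in
    the two partners, over a pose set.

    ``weighting='mayer'`` weights each pose by e^{-beta U} - 1
    (normalised); ``'none'`` counts poses equally.  Returns
    (bin_centers, normalised histogram).
    """
    central_c = central.centered()
    test_c = test.centered()
    site_c = _sidechain_centroid(central_c, residue_index)
    site_t_local = _sidechain_centroid(test_c, residue_index)
    dists, weights = [], []
    beta = 1.0 / (KB * temperature)
    for p in poses:
        rot = Rotation.from_quat(p.orientation)
        site_t = rot.apply(site_t_local) + p.position
        dists.append(float(np.linalg.norm(site_t - site_c)))
        if weighting == "mayer":
            weights.append(math.expm1(-beta * p.energy))
        elif weighting == "none":
            weights.append(1.0)
        else:
            raise ValueError("weighting must be 'none' or 'mayer'")
    h, edges = np.histogram(dists, bins=bins, weights=weights)
    total = h.sum()
    if total > 0:
        h = h / total
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, h
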