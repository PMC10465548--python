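"""Equilibrium configurations of rigid molecules in a periodic box.

Metropolis Monte Carlo with the package's pair energy (hard core +
scaled Lennard-Jones + screened electrostatics) generates the solution
configurations into which the test molecule is inserted.  Only the
equilibrium ensemble matters for chemical potentials, so single-molecule
translation/rotation moves with Metropolis acceptance are sufficient;
move sizes are auto-tuned toward a 30-50% acceptance rate during
equilibration only, so production sampling obeys detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .energy_model import EnergyParams, KB, molecule_pair_energy, transform_coords
from .structure_io import RigidMolecule

__all__ = [
    "AVOGADRO",
    "SolutionConfig",
    "Trajectory",
    "concentration_mg_ml",
    "init_config",
    "run_sampler",
    "pair_distribution",
]

AVOGADRO = 6.02214076e23


@dataclass
class SolutionConfig:
    """N rigid-body poses in a periodic cubic box.

    ``poses`` is a list of (position [Å], quaternion [x,y,z,w]) pairs;
    positions are wrapped into [0, box_side).
    """

    box_side: float
    poses: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_copies(self) -> int:
        return len(self.poses)

    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.poses]) if self.poses else np.zeros((0, 3))

    def concentration(self, mass: float) -> float:
        return concentration_mg_ml(self.n_copies, self.box_side, mass)


@dataclass
class Trajectory:
    """Snapshots of a sampling run at a fixed interval."""

    snapshots: list[SolutionConfig]
    sampling_interval: int  # sweeps between snapshots
    seed: int
    energies: list[float] = field(default_factory=list)  # total energy per snapshot
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.snapshots:
            n0, b0 = self.snapshots[0].n_copies, self.snapshots[0].box_side
            for s in self.snapshots:
                if s.n_copies != n0 or abs(s.box_side - b0) > 1e-9:
                    raise ValueError("trajectory snapshots must share N and box")


def concentration_mg_ml(n: int, box_side: float, mass: float) -> float:
    """Concentration of n copies of a molecule of given mass (Da) in mg/ml."""
    if box_side <= 0:
        raise ValueError("box_side must be > 0")
    if n < 0:
        raise ValueError("n must be >= 0")
    volume_ml = box_side**3 * 1e-24
    return n * mass * 1e3 / (AVOGADRO * volume_ml)


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _pair_clash(mol: RigidMolecule, pose_i, pose_j, box: float) -> bool:
    ci = transform_coords(mol, pose_i)
    cj = transform_coords(mol, pose_j)
    d = ci[:, None, :] - cj[None, :, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)
    contact = (mol.lj_sigmas[:, None] + mol.lj_sigmas[None, :]) / 2.0
    return bool(np.any(r < contact))


def init_config(
    n: int,
    box_side: float,
    mol: RigidMolecule,
    seed: int,
    max_attempts: int = 1_000_000,
) -> SolutionConfig:
    """Random sequential clash-free insertion of n copies; deterministic per seed."""
    rng = np.random.default_rng(seed)
    mol_c = mol.centered()
    poses: list[tuple[np.ndarray, np.ndarray]] = []
    attempts = 0
    while len(poses) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not insert copy {len(poses) + 1}/{n} within {max_attempts} "
                "attempts; lower the concentration or enlarge the box"
            )
        attempts += 1
        pos = rng.uniform(0.0, box_side, size=3)
        quat = _random_quat(rng)
        cand = (pos, quat)
        if any(_pair_clash(mol_c, cand, p, box_side) for p in poses):
            continue
        poses.append(cand)
    return SolutionConfig(box_side=box_side, poses=poses)


def total_energy(config: SolutionConfig, mol: RigidMolecule, params: EnergyParams) -> float:
    """Sum of pair energies over all distinct molecule pairs."""
    mol_c = mol.centered()
    total = 0.0
    for i in range(config.n_copies):
        for j in range(i + 1, config.n_copies):
            e = molecule_pair_energy(
                mol_c, config.poses[i], mol_c, config.poses[j], params, box_side=config.box_side
            )
            if e.steric_clash:
                return math.inf
            total += e.total
    return total


def run_sampler(
    config: SolutionConfig,
    mol: RigidMolecule,
    params: EnergyParams,
    n_sweeps: int,
    seed: int,
    n_equil: int = 0,
    sample_interval: int = 1,
    translation_sigma: float = 1.0,
    rotation_sigma: float = 0.3,
    temperature: float | None = None,
    tune: bool = True,
    interactions: bool = True,
) -> Trajectory:
    """Metropolis Monte Carlo on rigid-body poses.

    One sweep = N single-molecule trial moves (Gaussian translation plus a
    small axis-angle rotation).  Snapshots are collected every
    ``sample_interval`` sweeps after ``n_equil`` equilibration sweeps.
    With ``interactions=False`` every non-clashing move is accepted and
    clash checks are skipped entirely (ideal gas).
    """
    if translation_sigma <= 0 or rotation_sigma <= 0:
        raise ValueError("move sizes must be > 0")
    T = temperature if temperature is not None else params.temperature_ref
    beta = 1.0 / (KB * T)
    rng = np.random.default_rng(seed)
    mol_c = mol.centered()
    box = config.box_side
    poses = [(np.array(p, dtype=float), np.array(q, dtype=float)) for p, q in config.poses]
    n = len(poses)

    def _pair_e(pose_i, pose_j) -> float:
        e = molecule_pair_energy(mol_c, pose_i, mol_c, pose_j, params, box_side=box)
        return math.inf if e.steric_clash else e.total

    # pairwise energy matrix; row sums give each molecule's interaction energy
    e_pair = None
    if interactions:
        e_pair = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                e_pair[i, j] = e_pair[j, i] = _pair_e(poses[i], poses[j])

    snapshots: list[SolutionConfig] = []
    snap_energies: list[float] = []
    n_acc = n_try = 0
    t_sigma, r_sigma = translation_sigma, rotation_sigma

    for sweep in range(n_equil + n_sweeps):
        in_equil = sweep < n_equil
        for _ in range(n):
            k = int(rng.integers(n))
            old_pos, old_quat = poses[k]
            new_pos = np.mod(old_pos + rng.normal(scale=t_sigma, size=3), box)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(scale=r_sigma)
            dq = Rotation.from_rotvec(axis * angle)
            new_quat = (dq * Rotation.from_quat(old_quat)).as_quat()
            cand = (new_pos, new_quat)
            n_try += 1
            if not interactions:
                poses[k] = cand
                n_acc += 1
                continue
            new_row = np.array(
                [0.0 if j == k else _pair_e(cand, poses[j]) for j in range(n)]
            )
            e_new = float(new_row.sum())
            e_old = float(e_pair[k].sum())
            accept = False
            if not math.isinf(e_new):
                de = e_new - e_old
                if de <= 0 or rng.random() < math.exp(-beta * de):
                    accept = True
            if accept:
                poses[k] = cand
                e_pair[k, :] = new_row
                e_pair[:, k] = new_row
                n_acc += 1
        if in_equil and tune and n_try >= 50 * max(n, 1):
            rate = n_acc / n_try
            if rate < 0.30:
                t_sigma *= 0.8
                r_sigma *= 0.8
            elif rate > 0.50:
                t_sigma *= 1.2
                r_sigma *= 1.2
            n_acc = n_try = 0
        if not in_equil and (sweep - n_equil + 1) % sample_interval == 0:
            snap = SolutionConfig(
                box_side=box, poses=[(p.copy(), q.copy()) for p, q in poses]
            )
            snapshots.append(snap)
            snap_energies.append(float(e_pair.sum()) / 2.0 if interactions else 0.0)
    acc = {"rate": (n_acc / n_try) if n_try else 0.0, "translation_sigma": t_sigma, "rotation_sigma": r_sigma}
    return Trajectory(
        snapshots=snapshots, sampling_interval=sample_interval, seed=seed,
        energies=snap_energies, acceptance=acc,
    )


def pair_distribution(
    traj: Trajectory, r_bins: np.ndarray, min_snapshots: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Center-of-geometry radial distribution function g(r).

    Minimum-image pair distances, shell-normalised against the ideal-gas
    expectation.  Returns (bin_centers, g).
    """
    r_bins = np.asarray(r_bins, dtype=float)
    if np.any(np.diff(r_bins) <= 0):
        raise ValueError("r_bins must be strictly increasing")
    if len(traj.snapshots) < min_snapshots:
        raise ValueError(f"need at least {min_snapshots} snapshots")
    counts = np.zeros(len(r_bins) - 1)
    n = traj.snapshots[0].n_copies
    box = traj.snapshots[0].box_side
    for snap in traj.snapshots:
        pos = snap.positions()
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(n, k=1)
        counts += np.histogram(r[iu], bins=r_bins)[0]
    counts /= len(traj.snapshots)
    v = box**3
    shell = 4.0 / 3.0 * np.pi * (r_bins[1:] ** 3 - r_bins[:-1] ** 3)
    ideal = (n * (n - 1) / 2.0) * shell / v
    centers = 0.5 * (r_bins[1:] + r_bins[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return centers, g
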