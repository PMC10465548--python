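"""FFT translational scan of a rigid test molecule through a solution.

Given a configuration of rigid molecules in a periodic cubic box and one
orientation of a test molecule, the scan returns the test molecule's
interaction energy at every point of a cubic lattice plus a steric-clash
mask — the quantities from which both excess chemical potentials (Widom
insertion) and second virial coefficients (Mayer integration) follow.

The geometric combining rule (epsilon_ij = sqrt(eps_i eps_j),
sigma_ij = sqrt(sig_i sig_j)) factorises the Lennard-Jones sum into two
separable correlations with per-atom weights sqrt(eps)*sigma^6 and
sqrt(eps)*sigma^3 against truncated r^-12 and r^-6 kernels; screened
electrostatics is a third correlation of the charge grid against a
truncated Debye-Hückel kernel.  Steric clash is resolved exactly on the
lattice: test atoms are grouped by hard-core radius and, for each group,
solution atoms are stamped as balls of the summed contact radius, so a
positive cross-correlation means precisely that some atom pair sits
closer than the sum of its hard-core radii (to lattice snapping).

Kernels are capped at their one-voxel value; the capped region lies
inside the hard core whenever the lattice spacing is below the smallest
contact distance, so clash-free energies are never affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import fft as sfft
from scipy.spatial.transform import Rotation

from .energy_model import COULOMB_CONST, EnergyParams
from .structure_io import RigidMolecule

if TYPE_CHECKING:  # pragma: no cover
    from .sampler import SolutionConfig

__all__ = [
    "GridSpec",
    "EnergyLandscape",
    "SolutionFields",
    "build_solution_fields",
    "scan",
    "clash_free_fraction",
]


@dataclass(frozen=True)
class GridSpec:
    """Cubic periodic lattice covering the simulation box.

    ``n_per_dim = round(box_side / spacing)``; the effective spacing is
    then ``box_side / n_per_dim`` so the lattice tiles the box exactly.
    """

    box_side: float
    spacing: float = 0.6

    def __post_init__(self) -> None:
        if self.box_side <= 0 or self.spacing <= 0:
            raise ValueError("box_side and spacing must be > 0")

    @property
    def n_per_dim(self) -> int:
        return int(round(self.box_side / self.spacing))

    @property
    def h(self) -> float:
        """Effective lattice spacing in Å."""
        return self.box_side / self.n_per_dim

    @property
    def n_points(self) -> int:
        return self.n_per_dim**3


@dataclass
class EnergyLandscape:
    """Scan output: per-lattice-point clash mask and raw energy terms.

    ``nonpolar`` and ``electrostatic`` are the unscaled term sums; the
    scaled total is ``s1*nonpolar + s2*electrostatic``.  Values under the
    clash mask are meaningless (the true energy there is +inf).
    """

    grid: GridSpec
    clash_mask: np.ndarray  # bool (n,n,n)
    nonpolar: np.ndarray  # float (n,n,n), raw
    electrostatic: np.ndarray  # float (n,n,n), raw
    s1: float
    s2: float

    @property
    def n_clash_free(self) -> int:
        return int(self.clash_mask.size - np.count_nonzero(self.clash_mask))

    @property
    def energies(self) -> np.ndarray:
        """Scaled total energies at the clash-free lattice points (1-D)."""
        free = ~self.clash_mask
        return self.s1 * self.nonpolar[free] + self.s2 * self.electrostatic[free]

    def term_energies(self) -> tuple[np.ndarray, np.ndarray]:
        """(raw nonpolar, raw electrostatic) at clash-free points."""
        free = ~self.clash_mask
        return self.nonpolar[free], self.electrostatic[free]


def _min_image_r(grid: GridSpec) -> np.ndarray:
    """Minimum-image distance from the origin for every lattice point."""
    n, h = grid.n_per_dim, grid.h
    idx = np.arange(n)
    d1 = np.minimum(idx, n - idx) * h
    r2 = d1[:, None, None] ** 2 + d1[None, :, None] ** 2 + d1[None, None, :] ** 2
    return np.sqrt(r2)


_kernel_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _kernels_hat(grid: GridSpec, params: EnergyParams):
    """rFFTs of the truncated, one-voxel-capped r^-12, r^-6 and DH kernels."""
    key = (grid.n_per_dim, round(grid.h, 12), round(params.cutoff, 9),
           round(params.kappa, 12), round(params.dielectric, 9))
    if key in _kernel_cache:
        return _kernel_cache[key]
    r = _min_image_r(grid)
    h = grid.h
    rc = np.maximum(r, h)  # cap at one voxel
    inside = r < params.cutoff
    k6 = np.where(inside, rc**-6.0, 0.0)
    k12 = np.where(inside, rc**-12.0, 0.0)
    kdh = np.where(inside, COULOMB_CONST * np.exp(-params.kappa * rc) / (params.dielectric * rc), 0.0)
    out = (sfft.rfftn(k12), sfft.rfftn(k6), sfft.rfftn(kdh))
    if len(_kernel_cache) > 8:
        _kernel_cache.clear()
    _kernel_cache[key] = out
    return out


def _trilinear_deposit(grid_arr: np.ndarray, positions: np.ndarray, weights: np.ndarray, grid: GridSpec) -> None:
    """Deposit point weights onto the 8 surrounding voxels (periodic)."""
    n, h = grid.n_per_dim, grid.h
    g = positions / h
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                np.add.at(
                    grid_arr,
                    ((i0[:, 0] + dx) % n, (i0[:, 1] + dy) % n, (i0[:, 2] + dz) % n),
                    weights * w,
                )


_ball_cache: dict[tuple, np.ndarray] = {}


def _ball_offsets(radius: float, h: float) -> np.ndarray:
    """Integer lattice offsets with |offset*h| strictly < radius."""
    key = (round(radius, 9), round(h, 12))
    if key in _ball_cache:
        return _ball_cache[key]
    m = int(np.floor(radius / h)) + 1
    ax = np.arange(-m, m + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = (X**2 + Y**2 + Z**2) * h * h
    sel = r2 < radius**2 - 1e-9
    out = np.stack([X[sel], Y[sel], Z[sel]], axis=1)
    if len(_ball_cache) > 64:
        _ball_cache.clear()
    _ball_cache[key] = out
    return out


def _stamp_balls(field_arr: np.ndarray, centers: np.ndarray, radii: np.ndarray, grid: GridSpec) -> None:
    """Add 1 to every voxel strictly inside a ball around each (snapped) center."""
    n, h = grid.n_per_dim, grid.h
    snapped = np.rint(centers / h).astype(np.int64)
    for c, rad in zip(snapped, radii):
        off = _ball_offsets(float(rad), h)
        vox = (c[None, :] + off) % n
        np.add.at(field_arr, (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)


def _radius_classes(radii: np.ndarray) -> dict[float, np.ndarray]:
    """Group atom indices by hard-core radius (rounded to 1e-6 Å)."""
    out: dict[float, list[int]] = {}
    for i, r in enumerate(radii):
        out.setdefault(round(float(r), 6), []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class SolutionFields:
    """Fourier-space fields of one solution configuration.

    ``steric_hat`` maps each *test-atom* hard-core radius class to the
    rFFT of a field in which every solution atom is stamped as a ball of
    the summed contact radius; a positive cross-correlation with the
    delta grid of that test-atom class signals steric clash.
    """

    grid: GridSpec
    params: EnergyParams
    f12_hat: np.ndarray
    f6_hat: np.ndarray
    fel_hat: np.ndarray
    steric_hat: dict[float, np.ndarray]
    n_solution_atoms: int


def _solution_atom_arrays(config, mol: RigidMolecule):
    """All solution-atom coordinates and per-atom parameters, posed and wrapped."""
    from .energy_model import transform_coords

    box = config.box_side
    local = mol.centered()
    coords_list, n = [], len(config.poses)
    for pos, quat in config.poses:
        coords_list.append(transform_coords(local, (np.asarray(pos), quat)))
    if coords_list:
        coords = np.concatenate(coords_list, axis=0)
    else:
        coords = np.zeros((0, 3))
    coords = np.mod(coords, box)
    eps = np.tile(mol.lj_epsilons, n)
    sig = np.tile(mol.lj_sigmas, n)
    q = np.tile(mol.charges, n)
    return coords, eps, sig, q


def build_solution_fields(
    config,
    mol: RigidMolecule,
    grid: GridSpec,
    params: EnergyParams,
    test_radii: np.ndarray | None = None,
) -> SolutionFields:
    """Build the Fourier-space potential and steric fields of a configuration.

    ``test_radii``: hard-core radii of the test molecule's atoms (defaults
    to ``mol``'s own, the homotypic case); they determine the contact
    distances used by the exact steric correlation.
    """
    if abs(config.box_side - grid.box_side) > 1e-9:
        raise ValueError("configuration box and grid box differ")
    n = grid.n_per_dim
    coords, eps, sig, q = _solution_atom_arrays(config, mol)
    if coords.shape[0] and (np.any(coords < -1e-9) or np.any(coords > grid.box_side + 1e-9)):
        raise ValueError("solution atom outside the periodic box")

    a_grid = np.zeros((n, n, n))
    b_grid = np.zeros((n, n, n))
    q_grid = np.zeros((n, n, n))
    if coords.shape[0]:
        _trilinear_deposit(a_grid, coords, np.sqrt(eps) * sig**6, grid)
        _trilinear_deposit(b_grid, coords, np.sqrt(eps) * sig**3, grid)
        _trilinear_deposit(q_grid, coords, q, grid)

    k12_hat, k6_hat, kdh_hat = _kernels_hat(grid, params)
    f12_hat = sfft.rfftn(a_grid) * k12_hat
    f6_hat = sfft.rfftn(b_grid) * k6_hat
    fel_hat = sfft.rfftn(q_grid) * kdh_hat

    if test_radii is None:
        test_radii = mol.core_radii
    steric_hat: dict[float, np.ndarray] = {}
    sol_radii = sig / 2.0
    for cls in sorted({round(float(r), 6) for r in test_radii}):
        s_field = np.zeros((n, n, n))
        if coords.shape[0]:
            _stamp_balls(s_field, coords, sol_radii + cls, grid)
        steric_hat[cls] = sfft.rfftn(s_field)
    return SolutionFields(
        grid=grid, params=params, f12_hat=f12_hat, f6_hat=f6_hat,
        fel_hat=fel_hat, steric_hat=steric_hat, n_solution_atoms=coords.shape[0],
    )


def scan(
    test: RigidMolecule,
    orientation,
    fields: SolutionFields,
    grid: GridSpec,
    params: EnergyParams,
) -> EnergyLandscape:
    """Energy landscape of one test-molecule orientation over the lattice.

    The landscape value at lattice point R is the interaction energy of
    the test molecule with its geometric center at R.  Orientation may be
    a scipy Rotation, a quaternion, or None (identity).
    """
    if grid.n_per_dim != fields.grid.n_per_dim or abs(grid.h - fields.grid.h) > 1e-12:
        raise ValueError("scan grid does not match the fields' grid")
    n, shape = grid.n_per_dim, (grid.n_per_dim,) * 3
    if orientation is None:
        rot = None
    elif isinstance(orientation, Rotation):
        rot = orientation
    else:
        rot = Rotation.from_quat(np.asarray(orientation, dtype=float))
    local = test.coords - test.center
    if rot is not None:
        local = rot.apply(local)
    pos = np.mod(local, grid.box_side)

    eps, sig, q = test.lj_epsilons, test.lj_sigmas, test.charges
    a_grid = np.zeros(shape)
    b_grid = np.zeros(shape)
    q_grid = np.zeros(shape)
    _trilinear_deposit(a_grid, pos, np.sqrt(eps) * sig**6, grid)
    _trilinear_deposit(b_grid, pos, np.sqrt(eps) * sig**3, grid)
    _trilinear_deposit(q_grid, pos, q, grid)

    nonpolar = sfft.irfftn(
        4.0 * (np.conj(sfft.rfftn(a_grid)) * fields.f12_hat
               - np.conj(sfft.rfftn(b_grid)) * fields.f6_hat),
        s=shape,
    )
    elec = sfft.irfftn(np.conj(sfft.rfftn(q_grid)) * fields.fel_hat, s=shape)

    clash = np.zeros(shape, dtype=bool)
    classes = _radius_classes(test.core_radii)
    snapped = np.rint(pos / grid.h).astype(np.int64) % n
    for cls, atom_ids in classes.items():
        if cls not in fields.steric_hat:
            raise ValueError(
                f"fields lack a steric layer for test radius {cls}; rebuild with test_radii"
            )
        delta = np.zeros(shape)
        np.add.at(delta, (snapped[atom_ids, 0], snapped[atom_ids, 1], snapped[atom_ids, 2]), 1.0)
        corr = sfft.irfftn(np.conj(sfft.rfftn(delta)) * fields.steric_hat[cls], s=shape)
        clash |= corr > 0.5
    return EnergyLandscape(
        grid=grid, clash_mask=clash, nonpolar=nonpolar, electrostatic=elec,
        s1=params.s1, s2=params.s2,
    )


def clash_free_fraction(landscapes) -> float:
    """Pooled clash-free fraction over one or more landscapes.

    f_CF is treated as a single constant over configurations and
    orientations (its fluctuations are negligible compared to those of
    the Boltzmann average).
    """
    landscapes = list(landscapes) if not isinstance(landscapes, EnergyLandscape) else [landscapes]
    if not landscapes:
        raise ValueError("need at least one landscape")
    free = sum(ls.n_clash_free for ls in landscapes)
    total = sum(ls.clash_mask.size for ls in landscapes)
    return free / total
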