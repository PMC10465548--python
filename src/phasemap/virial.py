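"""Second virial coefficients by Mayer-function integration (FMAPB2).

A single central copy sits in a periodic box large enough that images
cannot interact; the test copy is scanned over the translational lattice
for a deterministic covering of SO(3).  Each lattice point contributes
the Mayer function f = exp(-beta*U) - 1, with clashed points
contributing exactly -1, so one energy histogram (plus the clash count)
yields B2 at every temperature:

    B2 = -(V/2) <f(R, Omega)>

The steric-only coefficient B2_st = (V/2) * clash fraction defines the
steric volume V_st = B2_st/4 used by the Vliegenthart-Lekkerkerker rule
B2(Tc)/V_st ~ -6.  B2 is reported both in Å^3 per molecule pair and in
the per-mass convention mol*ml/g^2 (x 1e-24 * N_A / M^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.spatial.transform import Rotation
from scipy.stats import ttest_ind

from .energy_model import EnergyParams, KB
from .fmap_grid import GridSpec, build_solution_fields, scan
from .sampler import AVOGADRO, SolutionConfig
from .structure_io import RigidMolecule, molecule_mass
from .widom_mu import ENERGY_CLIP, _bin_energies

__all__ = [
    "B2Result",
    "deterministic_orientations",
    "fmapb2",
    "steric_volume",
    "fmapb23_average",
    "group_compare",
]

SAVE_THRESHOLD_B2 = -6.0  # kcal/mol

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def deterministic_orientations(angular_resolution: float = 6.0) -> Rotation:
    """Deterministic covering of SO(3) at a requested angular resolution.

    The covering is a product of a Fibonacci lattice on the sphere of
    frame z-axes (count 4*pi/res^2, poles included so the identity is a
    member) with a uniform ring of in-plane spins (count 360/res).  At
    6 degrees this yields 1146 x 60 = 68760 rotations; the count scales
    as resolution^-3.
    """
    if not (2.0 <= angular_resolution <= 30.0):
        raise ValueError("angular resolution must lie in [2, 30] degrees")
    res = math.radians(angular_resolution)
    n_psi = int(round(2.0 * math.pi / res))
    n_sph = int(round(4.0 * math.pi / res**2))
    i = np.arange(n_sph)
    # poles included: cos(theta) from +1 to -1 inclusive
    cos_t = 1.0 - 2.0 * i / (n_sph - 1)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.where(i == 0, 0.0, i * _GOLDEN_ANGLE)
    psi = np.arange(n_psi) * res

    th = np.repeat(theta, n_psi)
    ph = np.repeat(phi, n_psi)
    ps = np.tile(psi, n_sph)
    # intrinsic z-y-z Euler rotations: R = Rz(phi) Ry(theta) Rz(psi)
    return Rotation.from_euler("zyz", np.stack([ph, th, ps], axis=1))


@dataclass
class B2Result:
    """Second virial coefficient over a temperature grid, from one scan set."""

    temperatures: np.ndarray  # K
    b2_molar: np.ndarray  # mol*ml/g^2
    b2_volume: np.ndarray  # Å^3 per molecule pair
    b2_st_volume: float  # Å^3
    b2_st_molar: float  # mol*ml/g^2
    mass: float  # Da
    n_clash: int
    n_total: int
    hist_origin: int
    hist_counts: np.ndarray
    hist_sums: np.ndarray
    bin_width: float
    saved_poses: list = field(default_factory=list)

    @property
    def vst_volume(self) -> float:
        """Steric volume B2_st/4 in Å^3."""
        return self.b2_st_volume / 4.0

    @property
    def vst_molar(self) -> float:
        """Steric volume B2_st/4 in the per-mass convention."""
        return self.b2_st_molar / 4.0

    def b2_over_vst(self) -> np.ndarray:
        return self.b2_volume / self.vst_volume


def _b2_from_hist(
    volume: float, n_total: int, n_clash: int,
    origin: int, counts: np.ndarray, sums: np.ndarray, bin_width: float, beta: float,
) -> float:
    """B2 in Å^3 from the clash count and clash-free energy histogram.

    Bin energies are the count-weighted means (first moments), so the
    Mayer sum is unbiased for the near-zero-energy bulk.
    """
    nz = counts > 0
    mayer_sum = -float(n_clash)
    if np.any(nz):
        u = sums[nz] / counts[nz]
        w = counts[nz].astype(float)
        # sum w*(e^{-beta u} - 1), done stably
        mayer_sum += float(np.exp(logsumexp(-beta * u, b=w))) - w.sum()
    return -0.5 * volume * mayer_sum / n_total


def _to_molar(b2_volume: float, mass: float) -> float:
    return b2_volume * 1e-24 * AVOGADRO / mass**2


def fmapb2(
    central: RigidMolecule,
    test: RigidMolecule | None = None,
    box_side: float = 200.0,
    grid: GridSpec | None = None,
    orientations: Rotation | None = None,
    params: EnergyParams | None = None,
    temperatures: np.ndarray | None = None,
    bin_width: float = 0.016,
    save_threshold: float = SAVE_THRESHOLD_B2,
) -> B2Result:
    """Mayer-function B2 between a central and a test copy.

    Defaults: homotypic pair (test = central), 200 Å box, 6-degree
    deterministic orientation covering, temperatures -10..60 °C.
    """
    if test is None:
        test = central
    if params is None:
        params = EnergyParams()
    if grid is None:
        grid = GridSpec(box_side=box_side, spacing=0.6)
    if abs(grid.box_side - box_side) > 1e-9:
        box_side = grid.box_side
    min_box = 2.0 * (central.radius() + test.radius() + params.cutoff)
    if box_side < min(min_box, 2.0 * params.cutoff):
        raise ValueError(
            f"box side {box_side} Å too small: periodic images of the pair can "
            f"interact (need >= {min_box:.1f} Å)"
        )
    if orientations is None:
        orientations = deterministic_orientations(6.0)
    if temperatures is None:
        temperatures = 273.15 + np.arange(-10.0, 61.0, 1.0)
    temperatures = np.asarray(temperatures, dtype=float)

    from .pose_analysis import PoseRecord

    center = np.full(3, box_side / 2.0)
    config = SolutionConfig(
        box_side=box_side, poses=[(center, np.array([0.0, 0.0, 0.0, 1.0]))]
    )
    fields = build_solution_fields(config, central, grid, params, test_radii=test.core_radii)

    n_total = 0
    n_clash = 0
    merged_origin = None
    merged = None
    merged_sums = None
    saved: list = []
    for i_ori in range(len(orientations)):
        ori = orientations[i_ori]
        ls = scan(test, ori, fields, grid, params)
        n_total += ls.clash_mask.size
        n_clash += int(np.count_nonzero(ls.clash_mask))
        energies = ls.energies
        if len(energies):
            o, c, s = _bin_energies(energies, bin_width)
            if merged is None:
                merged_origin, merged, merged_sums = o, c.copy(), s.copy()
            else:
                lo = min(merged_origin, o)
                hi = max(merged_origin + len(merged), o + len(c))
                out = np.zeros(hi - lo, dtype=np.int64)
                out_s = np.zeros(hi - lo)
                out[merged_origin - lo : merged_origin - lo + len(merged)] += merged
                out_s[merged_origin - lo : merged_origin - lo + len(merged)] += merged_sums
                out[o - lo : o - lo + len(c)] += c
                out_s[o - lo : o - lo + len(c)] += s
                merged_origin, merged, merged_sums = lo, out, out_s
            low = energies < save_threshold
            if np.any(low):
                free_idx = np.flatnonzero(~ls.clash_mask.ravel())[low]
                pos = np.array(np.unravel_index(free_idx, ls.clash_mask.shape)).T * grid.h
                # report test-center positions relative to the central copy
                pos = np.mod(pos - center + box_side / 2.0, box_side) - box_side / 2.0
                for p, e_val in zip(pos, energies[low]):
                    saved.append(
                        PoseRecord(position=p, orientation=ori.as_quat(),
                                   energy=float(e_val), source="fmapb2")
                    )
    if merged is None:
        merged_origin, merged, merged_sums = 0, np.zeros(1, dtype=np.int64), np.zeros(1)

    volume = box_side**3
    mass = _safe_mass(central)
    b2_st_vol = 0.5 * volume * n_clash / n_total
    b2_vol = np.array([
        _b2_from_hist(volume, n_total, n_clash, merged_origin, merged, merged_sums,
                      bin_width, 1.0 / (KB * T))
        for T in temperatures
    ])
    return B2Result(
        temperatures=temperatures,
        b2_molar=np.array([_to_molar(v, mass) for v in b2_vol]),
        b2_volume=b2_vol,
        b2_st_volume=b2_st_vol,
        b2_st_molar=_to_molar(b2_st_vol, mass),
        mass=mass,
        n_clash=n_clash,
        n_total=n_total,
        hist_origin=merged_origin,
        hist_counts=merged,
        hist_sums=merged_sums,
        bin_width=bin_width,
        saved_poses=saved,
    )


def _safe_mass(mol: RigidMolecule) -> float:
    try:
        return molecule_mass(mol)
    except KeyError:
        # toy fixtures may use non-element names; per-mass units then refer
        # to a nominal unit mass
        return 1.0


def steric_volume(
    central: RigidMolecule,
    test: RigidMolecule | None = None,
    box_side: float = 200.0,
    grid: GridSpec | None = None,
    orientations: Rotation | None = None,
    params: EnergyParams | None = None,
) -> tuple[float, float]:
    """Steric volume V_st = B2_st/4, as (Å^3, mol*ml/g^2)."""
    res = fmapb2(
        central, test, box_side=box_side, grid=grid, orientations=orientations,
        params=params, temperatures=np.array([298.0]),
    )
    return res.vst_volume, res.vst_molar


def fmapb23_average(
    library: list[RigidMolecule],
    temperatures: np.ndarray | None = None,
    **kwargs,
) -> np.ndarray:
    """Arithmetic mean of B2 over all ordered (central, test) structure pairs.

    All library members must share one sequence (same residue list); the
    structures may differ.  Returns the mean B2 in mol*ml/g^2 on the
    temperature grid.
    """
    if not library:
        raise ValueError("empty structure library")
    ref = [name for name, _ in library[0].residues]
    for m in library[1:]:
        if [name for name, _ in m.residues] != ref:
            raise ValueError("library structures must share the same sequence")
    results = []
    for central in library:
        for test in library:
            r = fmapb2(central, test, temperatures=temperatures, **kwargs)
            results.append(r.b2_molar)
    return np.mean(results, axis=0)


def group_compare(values_low, values_high) -> tuple[float, float]:
    """Welch unequal-variance two-sided t-test between two groups of B2 values."""
    a = np.asarray(values_low, dtype=float)
    b = np.asarray(values_high, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate-variance case: identical means are indistinguishable,
        # different means are separated with certainty
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
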