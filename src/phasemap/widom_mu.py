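"""Excess chemical potentials by Widom test-particle insertion.

Insertion energies from FFT scans over configurations x orientations are
pooled into a fine histogram H(U) (the sufficient statistic: one
histogram serves every temperature, since the energy function is frozen
at the reference temperature and only the Boltzmann beta changes).  The
excess chemical potential follows from

    exp(-beta mu_ex) = (f_CF / M_CF) * sum_U H(U) exp(-beta U)

with f_CF the pooled clash-free fraction and M_CF the clash-free count.
All Boltzmann sums go through log-sum-exp; beta*|U_min| can exceed 700.

Statistical errors come from Flyvbjerg-Petersen blocking applied to the
per-orientation average Boltzmann factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.spatial.transform import Rotation

from .energy_model import EnergyParams, KB
from .fmap_grid import GridSpec, build_solution_fields, scan
from .sampler import Trajectory
from .structure_io import RigidMolecule

__all__ = [
    "EnergyHistogram",
    "MuPoint",
    "random_orientations",
    "accumulate",
    "mu_ex_raw",
    "mu_ideal",
    "blocking_se_mean",
    "blocking_error",
]

DEFAULT_BIN_WIDTH = 0.016  # kcal/mol
SAVE_THRESHOLD_MU = -8.0  # kcal/mol; poses below are archived

# Energies above this bound are clamped into the top bin: their Boltzmann
# weight is below exp(-beta*500) at any temperature of interest, so the
# clamp only bounds the histogram's size, never the sums.
ENERGY_CLIP = 500.0


@dataclass
class MuPoint:
    """One excess-chemical-potential value (dimensionless beta*mu_ex)."""

    concentration: float  # mg/ml (nan if not set)
    temperature: float  # K
    beta_mu_ex: float
    stderr: float = 0.0
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass
class EnergyHistogram:
    """Binned clash-free insertion energies plus steric bookkeeping.

    Bin i holds energies rounding to center ``(origin + i) * bin_width``.
    ``per_orientation`` keeps, for each test orientation, its own compact
    (origin, counts, n_total) record so blocking errors and block-minimum
    statistics can be formed afterwards.  Separate raw nonpolar and
    electrostatic sub-histograms (2-D, coarse) allow re-scaling s1/s2
    without re-running any FFTs.
    """

    bin_width: float
    origin: int  # bin index of counts[0]
    counts: np.ndarray  # int64
    f_cf: float
    m_cf: int
    n_total: int  # all insertion attempts, clashed included
    n_configs: int
    n_orientations: int
    per_orientation: list = field(default_factory=list)
    saved_poses: list = field(default_factory=list)
    term_hist: tuple | None = None  # (np_edges, el_edges, counts2d) raw terms
    # per-bin energy sums (first moment); when present, Boltzmann and Mayer
    # sums use the count-weighted mean energy of each bin instead of its
    # nominal center, removing the coherent quantisation bias that the
    # near-zero-energy bulk would otherwise contribute
    energy_sums: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_cf <= 1.0):
            raise ValueError("f_CF must lie in [0, 1]")
        if int(self.counts.sum()) != self.m_cf:
            raise ValueError("histogram counts must sum to M_CF")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.origin + np.arange(len(self.counts))) * self.bin_width

    @property
    def representative_energies(self) -> np.ndarray:
        """Per-bin representative U: count-weighted mean when available."""
        centers = self.bin_centers
        if self.energy_sums is None:
            return centers
        out = centers.copy()
        occ = self.counts > 0
        out[occ] = self.energy_sums[occ] / self.counts[occ]
        return out

    @property
    def u_min_obs(self) -> float:
        nz = np.nonzero(self.counts)[0]
        if len(nz) == 0:
            raise ValueError("empty histogram")
        return float((self.origin + nz[0]) * self.bin_width)


def random_orientations(n: int, seed: int) -> Rotation:
    """n uniform random orientations (unit quaternions), reproducible per seed."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


def _bin_energies(energies: np.ndarray, bin_width: float) -> tuple[int, np.ndarray, np.ndarray]:
    """(origin, counts, energy sums) with bins centered at integer multiples
    of bin_width."""
    e = np.minimum(energies, ENERGY_CLIP)
    idx = np.rint(e / bin_width).astype(np.int64)
    origin = int(idx.min())
    counts = np.bincount(idx - origin)
    sums = np.bincount(idx - origin, weights=e)
    return origin, counts.astype(np.int64), sums


def accumulate(
    traj: Trajectory,
    test: RigidMolecule,
    n_orientations: int,
    grid: GridSpec,
    params: EnergyParams,
    seed: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    save_threshold: float = SAVE_THRESHOLD_MU,
    orientations: Rotation | None = None,
    keep_terms: bool = False,
    term_bin: float = 0.1,
) -> EnergyHistogram:
    """Pool insertion energies over all (configuration, orientation) pairs.

    The same orientation set (uniform random over SO(3), fixed by
    ``seed``) is scanned through every snapshot.  Poses with energy below
    ``save_threshold`` are archived as (snapshot, orientation, lattice
    position, energy) records.
    """
    from .pose_analysis import PoseRecord

    if not traj.snapshots:
        raise ValueError("empty trajectory")
    if orientations is None:
        orientations = random_orientations(n_orientations, seed)
    n_ori = len(orientations)

    merged_origin: int | None = None
    merged: np.ndarray | None = None
    merged_sums: np.ndarray | None = None
    per_ori_counts: list = [None] * n_ori
    per_ori_total = np.zeros(n_ori, dtype=np.int64)
    saved: list = []
    n_total = 0
    m_cf = 0
    np_all: list[np.ndarray] = []
    el_all: list[np.ndarray] = []

    def _merge(orig_a, cnt_a, sum_a, orig_b, cnt_b, sum_b):
        if cnt_a is None:
            return orig_b, cnt_b.copy(), sum_b.copy()
        lo = min(orig_a, orig_b)
        hi = max(orig_a + len(cnt_a), orig_b + len(cnt_b))
        out = np.zeros(hi - lo, dtype=np.int64)
        out_s = np.zeros(hi - lo)
        out[orig_a - lo : orig_a - lo + len(cnt_a)] += cnt_a
        out_s[orig_a - lo : orig_a - lo + len(cnt_a)] += sum_a
        out[orig_b - lo : orig_b - lo + len(cnt_b)] += cnt_b
        out_s[orig_b - lo : orig_b - lo + len(cnt_b)] += sum_b
        return lo, out, out_s

    for i_snap, snap in enumerate(traj.snapshots):
        fields = build_solution_fields(snap, _solution_molecule(traj, test), grid, params,
                                       test_radii=test.core_radii)
        for i_ori in range(n_ori):
            ori = orientations[i_ori]
            ls = scan(test, ori, fields, grid, params)
            energies = ls.energies
            n_total += ls.clash_mask.size
            m_cf += len(energies)
            per_ori_total[i_ori] += ls.clash_mask.size
            if len(energies):
                o, c, s = _bin_energies(energies, bin_width)
                merged_origin, merged, merged_sums = _merge(
                    merged_origin, merged, merged_sums, o, c, s
                )
                po, pc, ps = per_ori_counts[i_ori] or (None, None, None)
                per_ori_counts[i_ori] = _merge(po, pc, ps, o, c, s)
                if keep_terms:
                    np_e, el_e = ls.term_energies()
                    np_all.append(np_e)
                    el_all.append(el_e)
                low = energies < save_threshold
                if np.any(low):
                    free_idx = np.flatnonzero(~ls.clash_mask.ravel())[low]
                    pos = np.array(np.unravel_index(free_idx, ls.clash_mask.shape)).T * grid.h
                    for p, e_val in zip(pos, energies[low]):
                        saved.append(
                            PoseRecord(
                                position=p, orientation=ori.as_quat(),
                                energy=float(e_val), source="widom",
                                config_index=i_snap,
                            )
                        )

    if merged is None:
        raise ValueError("no clash-free insertions recorded")
    f_cf = m_cf / n_total
    per_ori = [
        {"origin": rec[0], "counts": rec[1], "sums": rec[2], "n_total": int(t)}
        for rec, t in zip(per_ori_counts, per_ori_total)
    ]
    term_hist = None
    if keep_terms and np_all:
        np_cat = np.concatenate(np_all)
        el_cat = np.concatenate(el_all)
        np_edges = np.arange(
            math.floor(np_cat.min() / term_bin) * term_bin,
            min(np_cat.max(), ENERGY_CLIP) + 2 * term_bin,
            term_bin,
        )
        el_edges = np.arange(
            math.floor(el_cat.min() / term_bin) * term_bin,
            min(el_cat.max(), ENERGY_CLIP) + 2 * term_bin,
            term_bin,
        )
        h2, _, _ = np.histogram2d(
            np.minimum(np_cat, ENERGY_CLIP), np.minimum(el_cat, ENERGY_CLIP),
            bins=(np_edges, el_edges),
        )
        term_hist = (np_edges, el_edges, h2)
    return EnergyHistogram(
        bin_width=bin_width, origin=merged_origin, counts=merged,
        f_cf=f_cf, m_cf=m_cf, n_total=n_total,
        n_configs=len(traj.snapshots), n_orientations=n_ori,
        per_orientation=per_ori, saved_poses=saved, term_hist=term_hist,
        energy_sums=merged_sums,
    )


def _solution_molecule(traj: Trajectory, test: RigidMolecule) -> RigidMolecule:
    """The molecule the solution is composed of (homotypic with the test)."""
    return test


def mu_ex_raw(hist: EnergyHistogram, temperature: float) -> MuPoint:
    """beta*mu_ex from the raw histogram at the requested temperature.

    Energies were computed at the reference temperature; only beta changes.
    """
    if hist.m_cf == 0:
        raise ValueError("histogram has no clash-free insertions")
    beta = 1.0 / (KB * temperature)
    nz = hist.counts > 0
    u = hist.representative_energies[nz]
    w = hist.counts[nz].astype(float)
    # ln[(f_CF/M_CF) sum H e^{-beta U}]
    log_sum = logsumexp(-beta * u, b=w)
    val = -(math.log(hist.f_cf) - math.log(hist.m_cf) + log_sum)
    if math.isnan(val):
        raise FloatingPointError("beta*mu_ex evaluated to NaN")
    return MuPoint(concentration=math.nan, temperature=temperature, beta_mu_ex=val)


def mu_ideal(rho: float, rho0: float = 1.0) -> float:
    """Ideal part beta*mu_id = ln(rho/rho0)."""
    if rho <= 0 or rho0 <= 0:
        raise ValueError("concentrations must be > 0")
    return math.log(rho / rho0)


def boltzmann_orientation_averages(hist: EnergyHistogram, temperature: float) -> np.ndarray:
    """Per-orientation average Boltzmann factor (clashed points count as 0).

    The mean of these over orientations estimates exp(-beta*mu_ex).
    """
    beta = 1.0 / (KB * temperature)
    out = np.zeros(len(hist.per_orientation))
    for i, rec in enumerate(hist.per_orientation):
        c = rec["counts"]
        nz = c > 0
        if not np.any(nz):
            continue
        u = rec["sums"][nz] / c[nz]
        out[i] = float(np.exp(logsumexp(-beta * u, b=c[nz].astype(float)))) / rec["n_total"]
    return out


def blocking_se_mean(values: np.ndarray, min_blocks: int = 16) -> float:
    """Flyvbjerg-Petersen blocking estimate of the standard error of the mean.

    Successive pair-averaging transformations; the reported SE is the
    largest level estimate among levels with at least ``min_blocks``
    blocks (a conservative plateau rule).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < min_blocks:
        raise ValueError(f"need at least {min_blocks} samples for blocking")
    if np.allclose(x, x[0]):
        return 0.0
    best = 0.0
    while len(x) >= min_blocks:
        se2 = np.var(x, ddof=1) / len(x)
        best = max(best, se2)
        if len(x) % 2 == 1:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    return math.sqrt(best)


def blocking_error(per_orientation_averages: np.ndarray, min_blocks: int = 16) -> float:
    """Standard error of beta*mu_ex from per-orientation Boltzmann averages.

    The SE of the mean Boltzmann factor m is propagated through -ln(m):
    d(beta*mu_ex) ~= SE(m)/m.
    """
    x = np.asarray(per_orientation_averages, dtype=float)
    se = blocking_se_mean(x, min_blocks=min_blocks)
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError("mean Boltzmann factor must be positive")
    return se / m
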