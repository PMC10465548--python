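import math

import numpy as np
import pytest

from phasemap.energy_model import EnergyParams, KB, molecule_pair_energy
from phasemap.fixtures import ToySpec, make_toy
from phasemap.fmap_grid import GridSpec
from phasemap.sampler import SolutionConfig, Trajectory
from phasemap.widom_mu import (
    EnergyHistogram,
    accumulate,
    blocking_error,
    blocking_se_mean,
    boltzmann_orientation_averages,
    mu_ex_raw,
    mu_ideal,
    random_orientations,
)

IDENT = np.array([0.0, 0.0, 0.0, 1.0])


def _traj(box, position_sets):
    snaps = [
        SolutionConfig(box_side=box, poses=[(np.asarray(p, float), IDENT) for p in ps])
        for ps in position_sets
    ]
    return Trajectory(snapshots=snaps, sampling_interval=1, seed=0)


def _hist_from_counts(bin_width, origin, counts, f_cf=1.0, n_total=None):
    counts = np.asarray(counts, dtype=np.int64)
    m_cf = int(counts.sum())
    return EnergyHistogram(
        bin_width=bin_width, origin=origin, counts=counts, f_cf=f_cf,
        m_cf=m_cf, n_total=n_total or m_cf, n_configs=1, n_orientations=1,
    )


class TestAccumulate:
    def test_empty_box(self, sphere, params_default):
        grid = GridSpec(box_side=20.0, spacing=1.0)
        traj = _traj(20.0, [[]])
        hist = accumulate(traj, sphere, 2, grid, params_default, seed=1)
        assert hist.f_cf == 1.0
        assert hist.m_cf == grid.n_points * 2
        nz = np.nonzero(hist.counts)[0]
        assert len(nz) == 1
        assert (hist.origin + nz[0]) * hist.bin_width == 0.0

    def test_matches_exhaustive_enumeration(self, dumbbell, params_nosalt):
        """Histogram equals brute-force enumeration of every
        (config, orientation, lattice point) insertion energy."""
        box, h = 16.0, 2.0
        grid = GridSpec(box_side=box, spacing=h)
        position_sets = [
            [[4.0, 4.0, 4.0], [12.0, 10.0, 6.0]],
            [[8.0, 8.0, 8.0], [2.0, 12.0, 4.0]],
        ]
        traj = _traj(box, position_sets)
        # lattice-preserving orientations keep every atom on a grid point,
        # where the scan is exact rather than exact-to-rasterisation
        from scipy.spatial.transform import Rotation

        oris = Rotation.from_euler("zyx", [[0, 0, 0], [90, 0, 0], [0, 90, 0]], degrees=True)
        n_ori = len(oris)
        hist = accumulate(traj, dumbbell, n_ori, grid, params_nosalt, seed=5,
                          orientations=oris)

        molc = dumbbell.centered()
        n = grid.n_per_dim
        energies = []
        n_total = 0
        for ps in position_sets:
            for i_ori in range(n_ori):
                rot = oris[i_ori]
                for idx in np.ndindex(n, n, n):
                    n_total += 1
                    R = np.array(idx, float) * h
                    clash = False
                    total = 0.0
                    for p in ps:
                        e = molecule_pair_energy(
                            molc, (np.asarray(p, float), None), molc, (R, rot.as_quat()),
                            params_nosalt, box_side=box,
                        )
                        if e.steric_clash:
                            clash = True
                            break
                        total += e.total
                    if not clash:
                        energies.append(total)
        assert hist.n_total == n_total
        assert hist.m_cf == len(energies)
        idx = np.rint(np.array(energies) / hist.bin_width).astype(int)
        expected = np.bincount(idx - idx.min())
        got = hist.counts[np.nonzero(hist.counts)[0][0]:][: len(expected)]
        np.testing.assert_array_equal(np.trim_zeros(hist.counts, "fb"),
                                      np.trim_zeros(expected, "fb"))

    def test_saves_low_energy_poses(self, params_default):
        # a deep dimer well: big epsilon makes contact energies < -8 kcal/mol
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=6.0, lj_epsilon=400.0))
        box = 24.0
        grid = GridSpec(box_side=box, spacing=1.0)
        traj = _traj(box, [[[12.0, 12.0, 12.0]]])
        hist = accumulate(traj, mol, 1, grid, params_default, seed=2)
        assert len(hist.saved_poses) > 0
        assert all(p.energy < -8.0 for p in hist.saved_poses)


class TestMuExRaw:
    def test_ideal_gas_zero(self):
        hist = _hist_from_counts(0.016, 0, [100])
        assert mu_ex_raw(hist, 298.0).beta_mu_ex == pytest.approx(0.0, abs=1e-12)

    def test_high_temperature_limit_is_steric(self):
        hist = _hist_from_counts(0.016, -50, [10, 0, 0, 20, 70], f_cf=0.8, n_total=125)
        very_hot = 1.0 / (KB * 1e-6)  # beta -> 0
        assert mu_ex_raw(hist, very_hot).beta_mu_ex == pytest.approx(-math.log(0.8), abs=1e-6)

    def test_two_bin_hand_value(self):
        # H = {1 at U=0, 1 at U=-1}, f_CF = 1, beta = 1
        bw = 1.0
        hist = _hist_from_counts(bw, -1, [1, 1])
        T = 1.0 / KB  # beta = 1
        expected = -math.log((1 + math.e) / 2.0)
        assert mu_ex_raw(hist, T).beta_mu_ex == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_attraction(self):
        h1 = _hist_from_counts(0.5, -2, [0, 5, 95])
        h2 = _hist_from_counts(0.5, -2, [1, 4, 95])  # one count moved lower
        assert mu_ex_raw(h2, 298.0).beta_mu_ex <= mu_ex_raw(h1, 298.0).beta_mu_ex

    def test_deep_well_no_overflow(self):
        hist = _hist_from_counts(1.0, -800, [1] + [0] * 799 + [10**6])
        val = mu_ex_raw(hist, 250.0).beta_mu_ex
        assert math.isfinite(val)


class TestMuIdeal:
    def test_reference(self):
        assert mu_ideal(5.0, 5.0) == 0.0

    def test_doubling(self):
        assert mu_ideal(2.0, 1.0) == pytest.approx(math.log(2))

    def test_additive_in_reference(self):
        assert mu_ideal(7.0, 1.0) == pytest.approx(mu_ideal(7.0, 3.0) + mu_ideal(3.0, 1.0))

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            mu_ideal(0.0, 1.0)


class TestBlocking:
    def test_iid_normal_close_to_naive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        se = blocking_se_mean(x)
        naive = x.std(ddof=1) / math.sqrt(len(x))
        assert se == pytest.approx(naive, rel=0.2)

    def test_constant_data_zero(self):
        assert blocking_se_mean(np.full(64, 3.7)) == 0.0

    def test_ar1_exceeds_naive(self):
        rng = np.random.default_rng(1)
        phi, n = 0.9, 4096
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        se = blocking_se_mean(x)
        naive = x.std(ddof=1) / math.sqrt(n)
        # effective sample size shrinks by (1+phi)/(1-phi) = 19 => SE up ~4.4x
        assert se > 2.0 * naive

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            blocking_se_mean(np.arange(8))

    def test_propagation_through_log(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(scale=0.05, size=512))
        err = blocking_error(x)
        assert err == pytest.approx(blocking_se_mean(x) / x.mean(), rel=1e-12)


class TestOrientationAverages:
    def test_mean_reproduces_mu(self, dumbbell, params_default):
        box = 16.0
        grid = GridSpec(box_side=box, spacing=2.0)
        traj = _traj(box, [[[4.0, 4.0, 4.0]], [[10.0, 6.0, 8.0]]])
        hist = accumulate(traj, dumbbell, 4, grid, params_default, seed=3)
        for T in (270.0, 298.0, 330.0):
            avgs = boltzmann_orientation_averages(hist, T)
            mu = mu_ex_raw(hist, T).beta_mu_ex
            # agreement up to within-bin dispersion of the per-orientation
            # and pooled first-moment representatives
            assert -math.log(avgs.mean()) == pytest.approx(mu, rel=1e-3)


class TestHistogramDiscretisation:
    def test_halving_bin_width_stable(self, dumbbell, params_default):
        box = 16.0
        grid = GridSpec(box_side=box, spacing=2.0)
        traj = _traj(box, [[[4.0, 4.0, 4.0]]])
        mus = []
        for bw in (0.016, 0.008):
            hist = accumulate(traj, dumbbell, 4, grid, params_default, seed=9, bin_width=bw)
            mus.append(mu_ex_raw(hist, 298.0).beta_mu_ex)
        assert abs(mus[0] - mus[1]) < 1e-3
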