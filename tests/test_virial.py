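import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phasemap.energy_model import EnergyParams, KB, molecule_pair_energy
from phasemap.fixtures import ToySpec, make_toy
from phasemap.fmap_grid import GridSpec
from phasemap.virial import (
    deterministic_orientations,
    fmapb2,
    fmapb23_average,
    group_compare,
    steric_volume,
)


def _angular_distance(R1, R2):
    """Geodesic angle between two rotations, radians."""
    return (R1.inv() * R2).magnitude()


class TestDeterministicOrientations:
    def test_identity_included(self):
        rots = deterministic_orientations(20.0)
        mags = rots.magnitude()
        assert mags.min() < 1e-9

    def test_count_scaling(self):
        n20 = len(deterministic_orientations(20.0))
        n10 = len(deterministic_orientations(10.0))
        assert n10 / n20 == pytest.approx(8.0, rel=0.15)

    def test_six_degree_count_matches_reference_scheme(self):
        # 4pi/res^2 sphere points x 360/res spins = 1146 x 60
        assert len(deterministic_orientations(6.0)) == 68760

    def test_covering_radius(self):
        """Every random rotation lies within ~1.5x the nominal resolution of
        some member of the set."""
        res_deg = 20.0
        rots = deterministic_orientations(res_deg)
        rng = np.random.default_rng(3)
        q = rng.normal(size=(200, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        probes = Rotation.from_quat(q)
        worst = 0.0
        for p in probes:
            rel = rots * p.inv()
            worst = max(worst, rel.magnitude().min())
        assert worst <= 1.5 * math.radians(res_deg)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            deterministic_orientations(1.0)


class TestFmapB2:
    def test_hard_sphere_excluded_volume(self):
        """B2 of a hard sphere equals (2pi/3) d^3 within 1% (d = contact)."""
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=8.0, lj_epsilon=0.0))
        box = 40.0
        res = fmapb2(
            mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.5),
            orientations=Rotation.identity(1), temperatures=np.array([298.0]),
        )
        analytic = (2.0 * math.pi / 3.0) * 8.0**3
        assert res.b2_st_volume == pytest.approx(analytic, rel=0.01)
        # purely steric: B2(T) = B2_st at any T
        assert res.b2_volume[0] == pytest.approx(res.b2_st_volume, rel=1e-9)

    def test_zero_interaction_zero_b2(self):
        ghost = make_toy(ToySpec(kind="sphere", lj_sigma=0.5, lj_epsilon=0.0))
        box = 30.0
        res = fmapb2(
            ghost, box_side=box, grid=GridSpec(box_side=box, spacing=1.0),
            orientations=Rotation.identity(1), temperatures=np.array([280.0, 298.0]),
        )
        # hard core shrunk to a point: excluded volume ~ one voxel
        assert abs(res.b2_volume[0]) <= box**3 / res.n_total

    def test_square_well_matches_radial_quadrature(self):
        """Attractive sphere: B2(T) agrees with the 1-D Mayer integral."""
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=5.0, lj_epsilon=1.0))
        box = 36.0
        params = EnergyParams()
        temps = np.array([260.0, 298.0, 340.0])
        res = fmapb2(
            mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.3),
            orientations=Rotation.identity(1), params=params, temperatures=temps,
        )
        molc = mol.centered()

        def u(r):
            e = molecule_pair_energy(molc, ((0, 0, 0), None), molc, ((r, 0, 0), None),
                                     params, box_side=box)
            return e.total

        for i, T in enumerate(temps):
            beta = 1.0 / (KB * T)
            rr = np.linspace(1e-4, params.cutoff + 2.0, 20001)
            mayer = np.where(rr < 5.0, -1.0, np.expm1(-beta * np.array([u(r) for r in rr])))
            b2_rad = -0.5 * np.trapezoid(mayer * 4.0 * np.pi * rr**2, rr)
            assert res.b2_volume[i] == pytest.approx(b2_rad, rel=0.02)

    def test_monotone_in_temperature_for_attractive_core(self):
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=5.0, lj_epsilon=1.5))
        box = 36.0
        temps = np.array([250.0, 280.0, 310.0, 340.0])
        res = fmapb2(mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.6),
                     orientations=Rotation.identity(1), temperatures=temps)
        assert np.all(np.diff(res.b2_volume) > 0)

    def test_box_too_small_errors(self, sphere):
        with pytest.raises(ValueError, match="too small"):
            fmapb2(sphere, box_side=10.0, grid=GridSpec(box_side=10.0, spacing=1.0),
                   orientations=Rotation.identity(1))

    def test_orientation_robustness(self):
        """Doubling the orientation count changes a toy B2 by < 1%.

        An attraction-dominated neutral dumbbell keeps |B2| large, so the
        comparison is not a cancellation of steric against attractive
        parts; 0.4 Å spacing keeps per-orientation rasterisation noise
        below the orientation-coverage effect being tested."""
        mol = make_toy(ToySpec(kind="charged_dumbbell", lj_sigma=3.0, lj_epsilon=1.5,
                               charge=0.0, separation=4.0))
        box = 32.0
        grid = GridSpec(box_side=box, spacing=0.4)
        r1 = fmapb2(mol, box_side=box, grid=grid,
                    orientations=deterministic_orientations(30.0),
                    temperatures=np.array([298.0]))
        r2 = fmapb2(mol, box_side=box, grid=grid,
                    orientations=deterministic_orientations(24.0),
                    temperatures=np.array([298.0]))
        assert r2.b2_volume[0] == pytest.approx(r1.b2_volume[0], rel=0.01)


class TestStericVolume:
    def test_definition(self):
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=8.0, lj_epsilon=0.0))
        box = 40.0
        vst_vol, vst_molar = steric_volume(
            mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.5),
            orientations=Rotation.identity(1),
        )
        res = fmapb2(mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.5),
                     orientations=Rotation.identity(1), temperatures=np.array([298.0]))
        assert vst_vol == res.b2_st_volume / 4.0

    def test_temperature_independent(self):
        mol = make_toy(ToySpec(kind="sphere", lj_sigma=5.0, lj_epsilon=1.0))
        box = 36.0
        res = fmapb2(mol, box_side=box, grid=GridSpec(box_side=box, spacing=0.6),
                     orientations=Rotation.identity(1),
                     temperatures=np.array([250.0, 350.0]))
        assert res.vst_volume == res.b2_st_volume / 4.0  # one number, no T axis


class TestFmapB23:
    def test_single_structure_library_equals_fmapb2(self, dumbbell):
        box = 36.0
        kw = dict(box_side=box, grid=GridSpec(box_side=box, spacing=0.8),
                  orientations=deterministic_orientations(30.0))
        mean = fmapb23_average([dumbbell], temperatures=np.array([298.0]), **kw)
        single = fmapb2(dumbbell, temperatures=np.array([298.0]), **kw)
        assert mean[0] == pytest.approx(single.b2_molar[0], rel=1e-12)

    def test_two_structures_mean_of_four_runs(self):
        a = make_toy(ToySpec(kind="charged_dumbbell", lj_sigma=3.0, lj_epsilon=0.2,
                             charge=1.0, separation=4.0))
        b = make_toy(ToySpec(kind="charged_dumbbell", lj_sigma=3.0, lj_epsilon=0.2,
                             charge=1.0, separation=5.0))
        box = 36.0
        kw = dict(box_side=box, grid=GridSpec(box_side=box, spacing=0.8),
                  orientations=deterministic_orientations(30.0))
        temps = np.array([298.0])
        mean = fmapb23_average([a, b], temperatures=temps, **kw)
        singles = [fmapb2(c, t, temperatures=temps, **kw).b2_molar[0]
                   for c in (a, b) for t in (a, b)]
        assert mean[0] == pytest.approx(np.mean(singles), rel=1e-12)

    def test_mixed_sequences_error(self, dumbbell, tetramer):
        with pytest.raises(ValueError, match="sequence"):
            fmapb23_average([dumbbell, tetramer])


class TestGroupCompare:
    def test_identical_groups(self):
        t, p = group_compare([1.0, 1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_welch_hand_value(self):
        # means -1.3 (SD 0.5, n=10) vs -2.1 (SD 0.3, n=5) => t ~ 3.9
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        a = (a - a.mean()) / a.std(ddof=1) * 0.5 - 1.3
        b = rng.normal(size=5)
        b = (b - b.mean()) / b.std(ddof=1) * 0.3 - 2.1
        t, p = group_compare(a, b)
        expected = (-1.3 - -2.1) / math.sqrt(0.5**2 / 10 + 0.3**2 / 5)
        assert t == pytest.approx(expected, rel=1e-9)
        assert t == pytest.approx(3.9, abs=0.1)

    def test_swap_symmetry(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 7.0]
        t1, p1 = group_compare(a, b)
        t2, p2 = group_compare(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
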