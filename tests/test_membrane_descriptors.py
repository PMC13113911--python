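import math

import numpy as np
import pytest

import chirobiophore as cb
from chirobiophore.errors import (DegenerateProfileError,
                                  UndefinedDescriptorError)
from chirobiophore.membrane_descriptors import (DDPMoments, DensityProfile,
                                                compute_ddp, compute_lai,
                                                compute_lai_weighted,
                                                compute_ots, ddp_moments,
                                                density_profile,
                                                orientation_tensor_skew)
from chirobiophore.structure_io import Atom, Structure
from chirobiophore.synthetic import (make_bundle, make_slab_cloud, mirror)


def cloud_from_z(z_values):
    return Structure([Atom(i + 1, "C", np.array([0.0, 0.0, z]), i, "A", "X")
                      for i, z in enumerate(z_values)])


def ddp_raw_oracle(profile):
    """Literal direct-sum evaluation of the raw skewness equation."""
    total = 0.0
    for zb, nb in zip(profile.bin_centers, profile.counts):
        total += (zb - profile.mu) ** 3 * nb
    return total / (profile.sigma ** 3 * profile.n_bins)


class TestDensityProfile:
    def test_symmetric_cloud_zero_mean(self):
        s = make_slab_cloud(1000, "symmetric_gaussian", seed=4)
        p = density_profile(s)
        assert p.mu == pytest.approx(0.0, abs=1e-10)

    def test_two_point_sigma_one(self):
        p = density_profile(cloud_from_z([-1.0] * 5 + [1.0] * 5), n_bins=2)
        assert p.sigma == pytest.approx(1.0)
        assert p.mu == pytest.approx(0.0, abs=1e-12)

    def test_three_bin_counts(self):
        p = density_profile(cloud_from_z([-1, -1, 0, 0, 1, 1]), n_bins=3)
        assert list(p.counts) == [2, 2, 2]

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateProfileError):
            density_profile(cloud_from_z([0.5]))
        with pytest.raises(DegenerateProfileError):
            density_profile(cloud_from_z([1.0, 1.0, 1.0]))


class TestDDP:
    def test_symmetric_cloud_zero_in_both_modes(self):
        s = make_slab_cloud(500, "symmetric_uniform", seed=9)
        p = density_profile(s)
        assert compute_ddp(p, "normalized") == pytest.approx(0.0, abs=1e-10)
        assert compute_ddp(p, "raw") == pytest.approx(0.0, abs=1e-8)

    def test_exponential_cloud_positive_skew(self):
        s = make_slab_cloud(2000, "shifted_exponential", seed=3)
        p = density_profile(s)
        assert compute_ddp(p, "normalized") > 0.5

    def test_raw_matches_direct_sum_oracle(self, rng):
        for _ in range(50):
            z = rng.normal(0, 5, 200) + rng.exponential(3, 200)
            p = density_profile(cloud_from_z(z), n_bins=30)
            got = compute_ddp(p, "raw")
            want = ddp_raw_oracle(p)
            assert got == pytest.approx(want, rel=1e-10)

    def test_z_negation_antisymmetry(self):
        s = make_slab_cloud(800, "shifted_exponential", seed=5)
        p = density_profile(s)
        pm = density_profile(mirror(s, "xy"))
        assert compute_ddp(pm) == pytest.approx(-compute_ddp(p), abs=1e-12)

    def test_bin_count_stability_on_smooth_cloud(self):
        s = make_slab_cloud(5000, "shifted_exponential", seed=12)
        vals = [compute_ddp(density_profile(s, n_bins=n))
                for n in (30, 50, 100)]
        ref = vals[1]
        assert all(abs(v - ref) / abs(ref) < 0.05 for v in vals)


class TestDDPMoments:
    def test_gaussian_kurtosis_three(self, rng):
        z = rng.standard_normal(100_000)
        m = ddp_moments(density_profile(cloud_from_z(z)))
        assert m.kurtosis == pytest.approx(3.0, abs=0.1)
        assert m.skewness == pytest.approx(0.0, abs=0.05)

    def test_two_point_closed_form(self):
        m = ddp_moments(density_profile(cloud_from_z([-1.0] * 4 + [1.0] * 4),
                                        n_bins=2))
        assert m.skewness == pytest.approx(0.0, abs=1e-12)
        assert m.kurtosis == pytest.approx(1.0)

    def test_norm_three_four_five(self):
        m = DDPMoments(mean_z=3.0, skewness=0.0, kurtosis=4.0)
        assert m.norm == pytest.approx(5.0)


class TestLAI:
    def test_three_up_one_down(self):
        assert compute_lai(cloud_from_z([1, 2, 3, -1])) == pytest.approx(0.5)

    def test_all_above_is_one(self):
        assert compute_lai(cloud_from_z([1, 2, 3])) == 1.0

    def test_midplane_atoms_excluded(self):
        assert compute_lai(cloud_from_z([0.0, 1.0, -1.0])) == 0.0

    def test_z_mirror_negation(self):
        s = make_slab_cloud(501, "shifted_exponential", seed=8)
        assert compute_lai(mirror(s, "xy")) == -compute_lai(s)

    def test_all_on_midplane_raises(self):
        with pytest.raises(UndefinedDescriptorError):
            compute_lai(cloud_from_z([0.0, 0.0]))

    @pytest.mark.parametrize("upper,lower,expected", [
        ([1, 1], [], 1.0), ([1], [1], 0.0), ([3], [1], 0.5),
        ([-3], [1], 0.5),      # magnitudes, not signs
    ])
    def test_weighted(self, upper, lower, expected):
        assert compute_lai_weighted(upper, lower) == pytest.approx(expected)

    def test_weighted_zero_weight_raises(self):
        with pytest.raises(UndefinedDescriptorError):
            compute_lai_weighted([0.0], [0.0])


class TestOTS:
    def test_vertical_helix_zero(self):
        s = make_bundle(1, 0.0, [1], seed=0)
        framed = cb.frame_structure(s)
        assert abs(compute_ots(framed)["ots"]) < 0.01

    def test_uniform_tilt_thirty_degrees(self):
        s = make_bundle(4, 30.0, [1, 1, 1, 1], seed=1)
        framed = cb.frame_structure(s)
        assert compute_ots(framed)["ots"] == pytest.approx(math.pi / 6,
                                                           abs=0.01)

    def test_alternating_handedness_cancels(self):
        s = make_bundle(4, 30.0, [1, -1, 1, -1], seed=2)
        framed = cb.frame_structure(s)
        assert compute_ots(framed)["ots"] == pytest.approx(0.0, abs=0.02)

    def test_x_mirror_negates(self):
        s = make_bundle(4, 25.0, [1, 1, -1, 1], seed=3)
        framed = cb.frame_structure(s)
        a = compute_ots(framed)["ots"]
        b = compute_ots(mirror(framed, "yz"))["ots"]
        assert a + b == pytest.approx(0.0, abs=1e-12)

    def test_no_helices_raises(self):
        with pytest.raises(UndefinedDescriptorError):
            compute_ots(make_slab_cloud(50, seed=1))


class TestTensorSkew:
    def test_cube_rod_disc_limits(self, rng):
        # cube: 8 corners, isotropic
        corners = np.array([[i, j, k] for i in (-1, 1) for j in (-1, 1)
                            for k in (-1, 1)], float)
        cube = Structure([Atom(i + 1, "C", c, i, "A", "X")
                          for i, c in enumerate(corners)])
        assert orientation_tensor_skew(cube) == pytest.approx(0.0,
                                                              abs=1e-10)
        rod = cloud_from_z(np.linspace(-5, 5, 20))
        assert orientation_tensor_skew(rod) == pytest.approx(1.0, abs=1e-10)
        ang = np.linspace(0, 2 * math.pi, 8, endpoint=False)
        disc_pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(8)], axis=1)
        disc = Structure([Atom(i + 1, "C", p, i, "A", "X")
                          for i, p in enumerate(disc_pts)])
        assert orientation_tensor_skew(disc) == pytest.approx(-0.5,
                                                              abs=1e-10)

    def test_range_on_random_clouds(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(30, 3)) * rng.uniform(0.5, 4, 3)
            s = Structure([Atom(i + 1, "C", p, i, "A", "X")
                           for i, p in enumerate(pts)])
            v = orientation_tensor_skew(s)
            assert -0.5 - 1e-12 <= v <= 1.0 + 1e-12

    def test_coincident_atoms_raise(self):
        s = cloud_from_z([1.0, 1.0, 1.0])
        s = s.with_coords(np.ones((3, 3)))
        with pytest.raises(UndefinedDescriptorError):
            orientation_tensor_skew(s)
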