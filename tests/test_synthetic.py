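"""Generator contracts: scaling laws, determinism, anchored medians."""
import numpy as np
import pytest

from fractalarbor import arbor as fa
from fractalarbor import morphometry as fm
from fractalarbor import synthetic as fs
from fractalarbor.errors import ParameterError


def _all_positions(arb):
    return np.array([n.position for n in arb.nodes.values()])


class TestHTree:
    def test_level_scaling_relation(self):
        spec = fs.HTreeSpec(D_target=1.4, levels=3, L_1=100.0)
        lengths = fs.htree_level_lengths(spec)
        assert lengths[1] == pytest.approx(100.0 / 2 ** (1 / 1.4))
        tree = fs.generate_htree(spec)
        measured = sorted({round(b.length, 6) for b in tree.branches}, reverse=True)
        assert measured == pytest.approx([100.0, lengths[1], lengths[2]])

    def test_twelve_levels_has_4095_branches(self):
        tree = fs.generate_htree(fs.HTreeSpec(D_target=1.4, levels=12, total_length=1000.0))
        assert len(tree.branches) == 2**12 - 1

    @pytest.mark.parametrize("D", [1.1, 1.4, 2.0, 3.0])
    def test_total_length_constant_across_D(self, D):
        tree = fs.generate_htree(fs.HTreeSpec(D_target=D, levels=10, total_length=1000.0))
        assert tree.total_length == pytest.approx(1000.0, abs=1e-6)

    def test_fork_angles_are_90_degrees(self, small_htree):
        angles = fm.measure_angles(small_htree)
        assert np.allclose(angles.phi, 90.0, atol=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            fs.HTreeSpec(D_target=0.0, levels=3, L_1=10.0)
        with pytest.raises(ParameterError):
            fs.HTreeSpec(D_target=1.4, levels=0, L_1=10.0)
        with pytest.raises(ParameterError):
            fs.HTreeSpec(D_target=1.4, levels=3)  # neither length given
        with pytest.raises(ParameterError):
            fs.HTreeSpec(D_target=1.4, levels=3, L_1=10.0, total_length=5.0)


class TestWeavingHTree:
    SPEC = dict(D_target=1.4, levels=6, total_length=500.0, weave_sigma=20.0, seed=42)

    def test_zero_sigma_identical_to_straight(self):
        spec = fs.HTreeSpec(D_target=1.4, levels=5, L_1=40.0, weave_sigma=0.0)
        a = fs.generate_htree(spec)
        b = fs.generate_weaving_htree(spec)
        assert np.allclose(_all_positions(a), _all_positions(b))

    def test_same_seed_reproducible(self):
        a = fs.generate_weaving_htree(fs.HTreeSpec(**self.SPEC))
        b = fs.generate_weaving_htree(fs.HTreeSpec(**self.SPEC))
        assert np.array_equal(_all_positions(a), _all_positions(b))

    def test_arc_length_preserved(self):
        tree = fs.generate_weaving_htree(fs.HTreeSpec(**self.SPEC))
        assert tree.total_length == pytest.approx(500.0, rel=1e-6)

    def test_weave_angle_spread_scales_with_sigma(self):
        spreads = []
        for sigma in (5.0, 40.0):
            spec = fs.HTreeSpec(D_target=1.4, levels=5, total_length=400.0,
                                weave_sigma=sigma, seed=3)
            tree = fs.generate_weaving_htree(spec)
            spreads.append(fm.measure_angles(tree).theta.std())
        assert spreads[1] > 2.0 * spreads[0]

    def test_bad_hurst_rejected(self):
        with pytest.raises(ParameterError):
            fs.HTreeSpec(D_target=1.4, levels=3, L_1=10.0, hurst=1.5)


class TestFractionalGaussianNoise:
    def test_persistence_matches_hurst(self, rng):
        x = fs.fractional_gaussian_noise(20000, 0.75, rng)
        rho1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert rho1 == pytest.approx(2**0.5 - 1, abs=0.05)  # 2^(2H-1) - 1

    def test_h_half_is_white(self, rng):
        x = fs.fractional_gaussian_noise(20000, 0.5, rng)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05
        assert x.var() == pytest.approx(1.0, rel=0.1)


class TestEqualLength:
    def test_equalize_three_level_tree(self):
        tree = fs.generate_htree(fs.HTreeSpec(D_target=1.4, levels=3, total_length=300.0))
        eq = fs.equalize_htree(tree)
        lengths = [b.length for b in eq.branches]
        assert np.allclose(lengths, 300.0 / 7)
        assert eq.total_length == pytest.approx(300.0)

    def test_single_branch_unchanged(self, cylinder_arbor):
        eq = fs.equalize_htree(cylinder_arbor)
        assert eq.branches[0].length == pytest.approx(10.0)

    def test_fork_angle_set_to_phi(self):
        tree = fs.generate_equal_length_htree(37.0, 4, branch_length=10.0)
        phi = fm.measure_angles(tree).phi
        assert np.allclose(phi, 37.0, atol=1e-6)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ParameterError):
            fs.generate_equal_length_htree(0.0, 4, branch_length=10.0)
        with pytest.raises(ParameterError):
            fs.generate_equal_length_htree(181.0, 4, branch_length=10.0)


class TestToyArbor:
    def test_sampled_medians_near_spec(self):
        spec = fs.ToyArborSpec(n_levels=9, seed=5)
        arb = fs.generate_toy_arbor(spec)
        angles = fm.measure_angles(arb)
        assert len(angles.theta) > 3000
        assert np.median(angles.theta) == pytest.approx(12.0, rel=0.10)
        assert np.median(angles.phi) == pytest.approx(37.0, rel=0.15)
        seg_lengths = np.array([s.length for s in arb.segments])
        assert np.median(seg_lengths) == pytest.approx(2.4, rel=0.10)
        widths = 2.0 * np.array([s.radius for s in arb.segments])
        assert np.median(widths) == pytest.approx(1.4, rel=0.10)

    def test_same_seed_identical(self):
        spec = fs.ToyArborSpec(n_levels=4, seed=9)
        a, b = fs.generate_toy_arbor(spec), fs.generate_toy_arbor(spec)
        assert np.array_equal(_all_positions(a), _all_positions(b))

    def test_one_level_is_single_path(self):
        arb = fs.generate_toy_arbor(fs.ToyArborSpec(n_levels=1, seed=2, n_primary=1))
        assert len(arb.branches) == 1


class TestEuclideanFixtures:
    def test_sphere_area_and_volume(self, icosphere):
        from fractalarbor.morphometry import hull_metrics
        assert icosphere.area() == pytest.approx(400 * np.pi, rel=0.01)
        hull = hull_metrics(icosphere.vertices)
        assert hull.volume == pytest.approx(4000 * np.pi / 3, rel=0.01)

    def test_sphere_is_watertight(self, icosphere):
        from fractalarbor.morphometry import model_volume
        # parity fill succeeds and finds a real interior
        assert model_volume(icosphere, 2.0) > 0.9 * (4000 * np.pi / 3)

    def test_line_arbor_is_one_straight_branch(self):
        line = fs.generate_line_arbor(100.0, 1.0, n_nodes=5)
        assert len(line.branches) == 1
        assert line.branches[0].length == pytest.approx(100.0)

    def test_cube_mesh(self):
        cube = fs.generate_cube_mesh(2.0)
        assert cube.area() == pytest.approx(24.0)
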