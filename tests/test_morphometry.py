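"""Branch statistics, angles, equalization, and cost metrics."""
import numpy as np
import pytest

from fractalarbor import arbor as fa
from fractalarbor import morphometry as fm
from fractalarbor import synthetic as fs
from fractalarbor._geom import rotation_about_axis
from fractalarbor.errors import ParameterError


class TestLevels:
    def test_primary_branches_are_level_one(self):
        nodes = [fa.CenterlineNode(1, [0, 0, 0], 1.0, None, fa.SOMA)]
        for k, d in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)], start=2):
            nodes.append(fa.CenterlineNode(k, 5.0 * np.array(d, float), 0.5, 1))
        arb = fm.assign_levels(fa.CenterlineArbor(nodes))
        assert [b.level for b in arb.branches] == [1, 1, 1]

    def test_htree_level_counts_double(self, small_htree):
        fm.assign_levels(small_htree)
        levels = np.array([b.level for b in small_htree.branches])
        assert levels.max() == 5
        assert np.array_equal(np.bincount(levels)[1:], [1, 2, 4, 8, 16])


class TestBranchLengthStats:
    def test_straight_htree_slope_is_minus_D(self):
        tree = fs.generate_htree(fs.HTreeSpec(D_target=1.4, levels=12, total_length=1000.0))
        stats = fm.branch_length_stats(tree)
        assert stats.loglog_slope == pytest.approx(-1.4, abs=1e-6)

    def test_two_point_slope_exact(self):
        # lengths 100 (x1) and 50 (x2): slope log(2)/log(0.5) = -1
        nodes = [
            fa.CenterlineNode(1, [0, 0, 0], 0.5, None, fa.SOMA),
            fa.CenterlineNode(2, [100, 0, 0], 0.5, 1),
            fa.CenterlineNode(3, [100, 50, 0], 0.5, 2),
            fa.CenterlineNode(4, [100, -50, 0], 0.5, 2),
        ]
        stats = fm.branch_length_stats(fa.CenterlineArbor(nodes))
        assert stats.loglog_slope == pytest.approx(-1.0, abs=1e-9)

    def test_equal_lengths_slope_undefined(self):
        tree = fs.generate_equal_length_htree(90.0, 3, branch_length=10.0)
        stats = fm.branch_length_stats(tree)
        assert stats.loglog_slope is None

    def test_histogram_counts_sum_to_branches(self, toy_arbor):
        stats = fm.branch_length_stats(toy_arbor)
        assert stats.hist_counts.sum() == len(toy_arbor.branches)
        assert np.all(stats.rel_lengths > 0) and np.all(stats.rel_lengths <= 1 + 1e-12)


class TestAngles:
    def test_collinear_chain_has_zero_weave(self):
        line = fs.generate_line_arbor(10.0, 1.0, n_nodes=5)
        angles = fm.measure_angles(line)
        assert np.allclose(angles.theta, 0.0, atol=1e-9)

    def test_right_angle_bend(self):
        arb = fa.CenterlineArbor([
            fa.CenterlineNode(1, [0, 0, 0], 0.5, None),
            fa.CenterlineNode(2, [5, 0, 0], 0.5, 1),
            fa.CenterlineNode(3, [5, 5, 0], 0.5, 2),
        ])
        angles = fm.measure_angles(arb)
        assert angles.theta == pytest.approx([90.0])

    def test_no_phi_for_soma_emanating_branches(self, fork_arbor):
        angles = fm.measure_angles(fork_arbor)
        # trunk emanates from soma: only the two fork branches carry phi
        assert len(angles.phi) == 2
        assert np.allclose(angles.phi, 100.0, atol=1e-9)

    def test_angles_in_valid_range(self, toy_arbor):
        angles = fm.measure_angles(toy_arbor)
        for vals in (angles.theta, angles.phi):
            assert np.all(vals >= 0.0) and np.all(vals <= 180.0)


class TestEqualize:
    def test_arithmetic_example(self):
        # branch lengths {2, 4, 6} -> all 4, total still 12
        nodes = [
            fa.CenterlineNode(1, [0, 0, 0], 0.5, None, fa.SOMA),
            fa.CenterlineNode(2, [2, 0, 0], 0.5, 1),
            fa.CenterlineNode(3, [2, 4, 0], 0.5, 2),
            fa.CenterlineNode(4, [2, -6, 0], 0.5, 2),
        ]
        eq = fm.equalize_branch_lengths(fa.CenterlineArbor(nodes))
        lengths = sorted(b.length for b in eq.branches)
        assert np.allclose(lengths, 4.0)
        assert eq.total_length == pytest.approx(12.0)

    def test_topology_and_angles_preserved(self, toy_arbor):
        eq = fm.equalize_branch_lengths(toy_arbor)
        assert len(eq.branches) == len(toy_arbor.branches)
        a0 = fm.measure_angles(toy_arbor)
        a1 = fm.measure_angles(eq)
        assert np.allclose(np.sort(a0.theta), np.sort(a1.theta), atol=1e-6)
        assert eq.total_length == pytest.approx(toy_arbor.total_length, rel=1e-9)


class TestHullMetrics:
    CUBE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                     [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], float)

    def test_unit_cube(self):
        hull = fm.hull_metrics(self.CUBE)
        assert hull.area == pytest.approx(6.0)
        assert hull.volume == pytest.approx(1.0)
        assert not hull.degenerate

    def test_icosphere_close_to_sphere(self, icosphere):
        hull = fm.hull_metrics(icosphere.vertices)
        assert hull.area == pytest.approx(400 * np.pi, rel=0.01)
        assert hull.volume == pytest.approx(4000 * np.pi / 3, rel=0.01)

    def test_interior_points_do_not_change_hull(self, rng):
        pts = np.vstack([self.CUBE, rng.uniform(0.2, 0.8, size=(50, 3))])
        hull = fm.hull_metrics(pts)
        assert hull.area == pytest.approx(6.0)
        assert hull.volume == pytest.approx(1.0)

    def test_coplanar_flagged_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        hull = fm.hull_metrics(pts)
        assert hull.degenerate
        assert hull.volume == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fm.hull_metrics(np.zeros((3, 3)))


class TestSurfaceArea:
    def test_isolated_cylinder_closed_form(self, cylinder_arbor):
        mesh = fa.mesh_from_centerline(cylinder_arbor)
        a_s = fm.surface_area(mesh, cylinder_arbor)
        # lateral + one end cap, 16-gon discretization
        expected = 2 * np.pi * 0.5 * 10 + np.pi * 0.25
        assert a_s == pytest.approx(expected, rel=0.03)

    def test_missing_mapping_falls_back_with_warning(self, icosphere):
        # mesh without a face→segment mapping but an arbor supplied
        with pytest.warns(UserWarning, match="segment mapping"):
            a = fm.surface_area(
                fa.TriangleMesh(icosphere.vertices, icosphere.faces),
                arbor=_dummy_arbor(),
            )
        assert a == pytest.approx(icosphere.area())

    def test_nested_tube_excluded(self):
        """Inner coaxial tube buried in an outer one contributes ~nothing."""
        nodes = [
            fa.CenterlineNode(1, [0, 0, 0], 0.5, None, fa.SOMA),
            fa.CenterlineNode(2, [0.01, 0, 0], 0.5, 1),
            fa.CenterlineNode(3, [10, 0, 0], 0.5, 2),
            fa.CenterlineNode(4, [1.0, 1e-4, 0], 0.3, 1),   # inner tube
            fa.CenterlineNode(5, [9.0, 1e-4, 0], 0.3, 4),
        ]
        arb = fa.CenterlineArbor(nodes)
        mesh = fa.mesh_from_centerline(arb)
        a_s = fm.surface_area(mesh, arb)
        outer_only = 2 * np.pi * 0.5 * 10 + np.pi * 0.25
        assert a_s == pytest.approx(outer_only, rel=0.05)
        # brute-force oracle: every inner-tube vertex is strictly inside the
        # outer cylinder (axis distance < 0.5, axial coordinate in (0, L))
        starts, ends, radii = arb.segment_arrays()
        inner_faces = mesh.segment_of_face >= 2  # segments 0,1 are the outer tube
        v = mesh.vertices[np.unique(mesh.faces[inner_faces])]
        axis = ends[0] - starts[0]
        for seg in range(2):
            s, e, r = starts[seg], ends[seg], radii[seg]
            u = (e - s) / np.linalg.norm(e - s)
            ax = (v - s) @ u
            d = np.linalg.norm(v - s - ax[:, None] * u, axis=1)
            if seg == 1:
                assert np.all(d < 0.5)

    def test_midpoint_subdivision_preserves_area(self, small_htree):
        """With no exclusions possible, A_s equals the raw mesh area."""
        mesh = fa.mesh_from_centerline(small_htree)
        # straight H-tree branches only overlap near forks; compare with a
        # single isolated cylinder where nothing can be excluded
        nodes = [fa.CenterlineNode(1, [0, 0, 0], 0.5, None),
                 fa.CenterlineNode(2, [10, 0, 0], 0.5, 1)]
        arb = fa.CenterlineArbor(nodes)
        m = fa.mesh_from_centerline(arb)
        assert fm.surface_area(m, arb) == pytest.approx(m.area(), rel=1e-12)


class TestModelVolume:
    def test_cylinder_within_five_percent(self):
        nodes = [fa.CenterlineNode(1, [0, 0, 0], 1.0, None),
                 fa.CenterlineNode(2, [10, 0, 0], 1.0, 1)]
        arb = fa.CenterlineArbor(nodes)
        mesh = fa.mesh_from_centerline(arb)
        v = fm.model_volume(mesh, 4.0, arbor=arb)
        assert v == pytest.approx(10 * np.pi, rel=0.05)

    def test_two_disjoint_cubes_additive(self):
        import trimesh
        a = trimesh.creation.box(extents=(1, 1, 1))
        b = trimesh.creation.box(extents=(1, 1, 1))
        b.apply_translation([3.0, 0.0, 0.0])
        merged = trimesh.util.concatenate([a, b])
        mesh = fa.TriangleMesh(np.asarray(merged.vertices), np.asarray(merged.faces))
        assert fm.model_volume(mesh, 4.0) == pytest.approx(2.0, rel=0.02)

    def test_overlapping_cylinders_counted_once(self):
        """Union volume of two crossing tubes < sum of the parts."""
        def tube(offset_z):
            nodes = [fa.CenterlineNode(1, [0, 0, offset_z], 1.0, None),
                     fa.CenterlineNode(2, [10, 0, offset_z], 1.0, 1)]
            return fa.CenterlineArbor(nodes)

        single = fm.model_volume(fa.mesh_from_centerline(tube(0.0)), 4.0, arbor=tube(0.0))
        # two tubes half-overlapping in z
        nodes = [
            fa.CenterlineNode(1, [0, 0, 0], 1.0, None, fa.SOMA),
            fa.CenterlineNode(2, [0.01, 0, 0], 1.0, 1),
            fa.CenterlineNode(3, [10, 0, 0], 1.0, 2),
            fa.CenterlineNode(4, [0.01, 0, 1.0], 1.0, 1),
            fa.CenterlineNode(5, [10, 0, 1.0], 1.0, 4),
        ]
        arb = fa.CenterlineArbor(nodes)
        union = fm.model_volume(fa.mesh_from_centerline(arb), 4.0, arbor=arb)
        assert single < union < 2.0 * single


class TestRigidInvariance:
    def test_metrics_invariant_under_rotation(self, fork_arbor):
        R = rotation_about_axis(np.array([0.3, -1.0, 0.7]) / np.linalg.norm([0.3, -1.0, 0.7]), 1.1)
        rot = fork_arbor.transformed(rotation=R, translation=np.array([5.0, -3.0, 2.0]))

        a0, a1 = fm.measure_angles(fork_arbor), fm.measure_angles(rot)
        assert np.allclose(np.sort(a0.phi), np.sort(a1.phi), atol=1e-9)
        assert rot.L_max == pytest.approx(fork_arbor.L_max, rel=1e-9)

        m0 = fa.mesh_from_centerline(fork_arbor)
        m1 = fa.mesh_from_centerline(rot)
        assert fm.surface_area(m1, rot) == pytest.approx(
            fm.surface_area(m0, fork_arbor), rel=1e-6)
        h0, h1 = fm.hull_metrics(m0.vertices), fm.hull_metrics(m1.vertices)
        assert h1.area == pytest.approx(h0.area, rel=1e-6)
        assert h1.volume == pytest.approx(h0.volume, rel=1e-6)
        v0 = fm.model_volume(m0, 4.0, arbor=fork_arbor)
        v1 = fm.model_volume(m1, 4.0, arbor=rot)
        # grid estimator: only statistically rotation invariant
        assert v1 == pytest.approx(v0, rel=0.10)


def _dummy_arbor():
    return fa.CenterlineArbor([
        fa.CenterlineNode(1, [0, 0, 0], 0.5, None),
        fa.CenterlineNode(2, [1, 0, 0], 0.5, 1),
    ])
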