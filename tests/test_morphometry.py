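"""Sholl profiles, branch statistics, colocalization geometry."""

import numpy as np
import pytest

from gbotools import morphometry as mm
from gbotools import synthetic as syn


def straight_skeleton(length=100.0, n_nodes=2, axis=0):
    """Soma at origin plus a straight process along one axis."""
    xyz = np.zeros((n_nodes + 1, 3))
    for i in range(1, n_nodes + 1):
        xyz[i, axis] = length * i / n_nodes
    return mm.Skeleton(
        ids=np.arange(1, n_nodes + 2),
        types=np.array([1] + [3] * n_nodes),
        xyz=xyz,
        radius=np.array([5.0] + [0.5] * n_nodes),
        parent_idx=np.array([-1] + list(range(n_nodes))),
    )


def dense_sholl_oracle(skeleton, radii, sample_step=0.01):
    """Count sign changes of (distance to soma - r) along densely sampled
    segments; independent of the analytic crossing count."""
    center = skeleton.soma_center
    counts = np.zeros(len(radii), dtype=int)
    for c, p in skeleton.edges():
        a, b = skeleton.xyz[p], skeleton.xyz[c]
        L = np.linalg.norm(b - a)
        n = max(int(np.ceil(L / sample_step)), 2)
        ts = np.linspace(0.0, 1.0, n + 1)
        pts = a[None] + ts[:, None] * (b - a)[None]
        d = np.linalg.norm(pts - center[None], axis=1)
        for k, r in enumerate(radii):
            signs = np.sign(d - r)
            nz = signs[signs != 0]
            counts[k] += int(np.sum(nz[1:] != nz[:-1]))
    return counts


class TestSholl:
    def test_single_ray_profile(self):
        skel = straight_skeleton(100.0, n_nodes=1)
        prof = mm.sholl(skel, radius_step=10.0, max_radius=120.0)
        expected = {r: (1 if r < 100 else 0) for r in prof.radii}
        assert {r: c for r, c in zip(prof.radii, prof.intersections)} == expected

    def test_soma_only_profile_is_zero(self):
        skel = mm.Skeleton(
            ids=np.array([1]), types=np.array([1]), xyz=np.zeros((1, 3)),
            radius=np.array([4.0]), parent_idx=np.array([-1]),
        )
        prof = mm.sholl(skel, radius_step=5.0, max_radius=20.0)
        assert np.all(prof.intersections == 0)

    def test_matches_dense_sampling_oracle(self, random_skeletons):
        for skel, _ in random_skeletons:
            prof = mm.sholl(skel, radius_step=5.0)
            oracle = dense_sholl_oracle(skel, prof.radii)
            assert np.array_equal(prof.intersections, oracle)

    def test_double_crossing_segment_counted_twice(self):
        # a chord whose endpoints are both outside r but which dips inside
        xyz = np.array([[0.0, 0, 0], [10.0, -8, 0], [10.0, 8, 0]])
        skel = mm.Skeleton(
            ids=np.array([1, 2, 3]), types=np.array([1, 3, 3]), xyz=xyz,
            radius=np.array([5.0, 0.5, 0.5]), parent_idx=np.array([-1, 0, 1]),
        )
        prof = mm.sholl(skel, radius_step=11.0, max_radius=12.0)
        # at r=11: radial edge crosses once; chord (|d|=12.8 ends, 10 mid) twice
        assert prof.intersections[0] == 3
        assert np.array_equal(
            prof.intersections, dense_sholl_oracle(skel, prof.radii)
        )

    def test_rigid_motion_invariance(self, random_skeletons):
        from scipy.spatial.transform import Rotation
        skel, _ = random_skeletons[3]
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -7.0, 2.0])
        moved = mm.Skeleton(
            ids=skel.ids, types=skel.types,
            xyz=skel.xyz @ R.T + shift,
            radius=skel.radius, parent_idx=skel.parent_idx,
        )
        a = mm.sholl(skel, radius_step=5.0, max_radius=80.0)
        b = mm.sholl(moved, radius_step=5.0, max_radius=80.0)
        assert np.array_equal(a.intersections, b.intersections)


class TestBranchStats:
    def test_single_segment_closed_form(self):
        skel = straight_skeleton(42.0)
        st = mm.branch_stats(skel)
        assert st.total_length == pytest.approx(42.0)
        assert st.n_primary == 1
        assert st.n_terminal == 1
        assert st.soma_area == pytest.approx(np.pi * 25.0)

    def test_two_level_binary_tree_terminals(self):
        _, truth = syn.simulate_skeleton(
            syn.SkeletonConfig(n_primary=2, branching_depth=3, jitter=0.0, seed=1)
        )
        assert truth["n_terminal"] == 8

    def test_matches_generator_truth(self, random_skeletons):
        for skel, truth in random_skeletons:
            st = mm.branch_stats(skel)
            assert st.total_length == pytest.approx(truth["total_length"], abs=1e-9)
            assert st.n_primary == truth["n_primary"]
            assert st.n_terminal == truth["n_terminal"]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="root|cycle"):
            mm.Skeleton(
                ids=np.array([1, 2]), types=np.array([1, 3]),
                xyz=np.zeros((2, 3)), radius=np.ones(2),
                parent_idx=np.array([1, 0]),
            )


class TestColocalization:
    def test_full_coverage_everywhere(self):
        skel = straight_skeleton(80.0)
        pts = np.array([[x, 0.0, 0.0] for x in np.arange(0, 80.5, 0.4)])
        res = mm.colocalization(skel, pts, eps=1.0, boundary=40.0)
        assert res.proximal_fraction == pytest.approx(1.0)
        assert res.distal_fraction == pytest.approx(1.0)
        assert res.total_fraction == pytest.approx(1.0)

    def test_proximal_only_coverage_at_40um_boundary(self):
        # radial 0-80 µm process, evidence points only along 0-40 µm
        skel = straight_skeleton(80.0, n_nodes=8)
        pts = np.array([[x, 0.0, 0.0] for x in np.arange(0, 39.5, 0.25)])
        res = mm.colocalization(skel, pts, eps=0.5, boundary=40.0)
        assert res.proximal_fraction == pytest.approx(1.0, abs=0.01)
        assert res.distal_fraction == pytest.approx(0.0, abs=0.01)

    def test_empty_point_cloud_gives_zero(self):
        skel = straight_skeleton(50.0)
        res = mm.colocalization(skel, np.empty((0, 3)))
        assert res.total_fraction == 0.0

    def test_length_weighted_consistency(self, random_skeletons):
        skel, _ = random_skeletons[2]
        pts, _ = syn.simulate_neurite_points(skel, 0.4, seed=3)
        res = mm.colocalization(skel, pts)
        combined = (
            res.proximal_fraction * res.proximal_length
            + res.distal_fraction * res.distal_length
        ) / (res.proximal_length + res.distal_length)
        assert combined == pytest.approx(res.total_fraction, abs=1e-9)

    def test_half_coverage_recovered_within_discretization(self):
        # single straight segment: the covered half is contiguous, so the
        # only discretization error sits at the 50 µm boundary
        skel = straight_skeleton(100.0, n_nodes=1)
        pts, truth = syn.simulate_neurite_points(skel, 0.5, offset=0.0, seed=0)
        res = mm.colocalization(skel, pts, eps=0.5, boundary=40.0, step=0.25)
        assert truth == pytest.approx(0.5)
        assert res.total_fraction == pytest.approx(0.5, abs=0.01)

    def test_halving_step_changes_little(self, random_skeletons):
        skel, _ = random_skeletons[1]
        pts, _ = syn.simulate_neurite_points(skel, 0.6, seed=4)
        f1 = mm.colocalization(skel, pts, step=0.5).total_fraction
        f2 = mm.colocalization(skel, pts, step=0.25).total_fraction
        assert abs(f1 - f2) < 0.01


class TestSWC:
    def test_roundtrip(self, tmp_path, random_skeletons):
        skel, _ = random_skeletons[0]
        path = tmp_path / "cell.swc"
        skel.write_swc(path)
        back = mm.Skeleton.read_swc(path)
        assert np.allclose(back.xyz, skel.xyz, atol=1e-5)
        assert np.array_equal(back.parent_idx, skel.parent_idx)
        assert np.array_equal(back.types, skel.types)

    def test_comments_ignored_and_malformed_rejected(self, tmp_path):
        good = tmp_path / "ok.swc"
        good.write_text("# comment\n1 1 0 0 0 5.0 -1\n2 3 10 0 0 0.5 1\n")
        skel = mm.Skeleton.read_swc(good)
        assert len(skel.ids) == 2
        bad = tmp_path / "bad.swc"
        bad.write_text("1 1 0 0 0 5.0\n")
        with pytest.raises(ValueError, match="malformed"):
            mm.Skeleton.read_swc(bad)
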