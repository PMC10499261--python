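"""Skeletonization and per-arbor measures: length, hull, branches, widths."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arbortrack.grid import VoxelGrid
from arbortrack.morphometry import (
    MultiComponentError,
    branch_width_profile,
    convex_hull_metrics,
    detect_swellings,
    enumerate_terminal_branches,
    skeletonize,
    total_cable_length,
    tree_width_profile,
)
from arbortrack.skeleton import SkeletonNode, SkeletonTree
from arbortrack.synth import ImagingParams, make_arbor_skeleton, rasterize_tree


def _path_tree(points, radius=0.5):
    nodes = [SkeletonNode(1, np.asarray(points[0], float), radius, None)]
    for k, p in enumerate(points[1:], start=2):
        nodes.append(SkeletonNode(k, np.asarray(p, float), radius, k - 1))
    return SkeletonTree(nodes)


@pytest.fixture(scope="module")
def phantom_params():
    return ImagingParams(
        field_xy_um=30.0, pixels_xy=96, z_step_um=0.5, depth_um=40.0,
        background_level=0.0, noise_model=("none", {}),
    )


class TestSkeletonize:
    def test_straight_tube_length_within_5_percent(self, phantom_params):
        pts = [(5.0 + t, 15.0, 20.0) for t in np.arange(0.0, 25.0 + 0.5, 0.5)]
        mask = rasterize_tree(_path_tree(pts), phantom_params)
        tree = skeletonize(mask)
        assert tree.cable_length() == pytest.approx(25.0, rel=0.05)

    def test_y_phantom_topology(self, phantom_params):
        stemp = [(15.1, 15.1, 2.0 + t) for t in np.arange(0.0, 15.5, 0.5)]
        nodes = [SkeletonNode(1, np.asarray(stemp[0]), 0.6, None)]
        for k, p in enumerate(stemp[1:], start=2):
            nodes.append(SkeletonNode(k, np.asarray(p), 0.6, k - 1))
        top = len(nodes)
        k = top
        for dx in (-1.0, 1.0):
            parent = top
            for t in np.arange(0.5, 10.5, 0.5):
                k += 1
                p = np.array(
                    [15.1 + dx * t * 0.6, 15.1 + dx * t * 0.35, 17.1 + t * 0.7]
                )
                nodes.append(SkeletonNode(k, p, 0.55, parent))
                parent = k
        mask = rasterize_tree(SkeletonTree(nodes), phantom_params)
        tree = skeletonize(mask)
        assert len(tree.leaves()) == 2
        assert len(tree.branch_points()) == 1

    def test_root_is_lowest_endpoint(self, phantom_params):
        pts = [(5.0 + t, 15.0, 5.0 + t) for t in np.arange(0.0, 20.0, 0.5)]
        tree = skeletonize(rasterize_tree(_path_tree(pts), phantom_params))
        zs = [n.position[2] for n in tree]
        assert tree.root.position[2] == pytest.approx(min(zs), abs=0.6)

    def test_self_touching_loop_broken_to_tree(self, phantom_params):
        # circle in the xy plane: the tube touches itself, forming a cycle
        theta = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        pts = [(15 + 6 * np.cos(t), 15 + 6 * np.sin(t), 20.0) for t in theta]
        pts.append(pts[0])  # close the loop
        mask = rasterize_tree(_path_tree(pts), phantom_params)
        tree = skeletonize(mask)  # SkeletonTree construction asserts acyclicity
        assert len(tree) > 50

    def test_multi_component_mask_rejected(self):
        arr = np.zeros((10, 20, 20), dtype=np.uint8)
        arr[2:4, 2:6, 2:6] = 1
        arr[7:9, 14:18, 14:18] = 1
        with pytest.raises(MultiComponentError, match="exclude_components"):
            skeletonize(VoxelGrid(arr, (0.5, 0.5, 0.5), kind="binary"))


class TestCableLength:
    def test_single_node_zero(self):
        tree = SkeletonTree([SkeletonNode(1, np.zeros(3), 0.5, None)])
        assert total_cable_length(tree) == 0.0

    def test_l_path_additivity(self):
        tree = _path_tree([(0, 0, 0), (30, 0, 0), (30, 40, 0)])
        assert total_cable_length(tree) == pytest.approx(70.0)

    def test_matches_edge_sum_oracle_on_random_tree(self):
        tree = make_arbor_skeleton(7, 6)
        oracle = 0.0
        for n in tree:  # brute-force edge-wise summation
            if n.parent is not None:
                oracle += float(np.linalg.norm(n.position - tree.node(n.parent).position))
        assert total_cable_length(tree) == pytest.approx(oracle, rel=1e-9)

    def test_invariant_under_reindexing_and_rotation(self):
        tree = make_arbor_skeleton(3, 5)
        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True)
        remap = {old: new for new, old in enumerate(sorted(tree.node_ids(), reverse=True), start=101)}
        rotated = SkeletonTree(
            SkeletonNode(
                remap[n.id],
                rot.apply(n.position),
                n.radius,
                None if n.parent is None else remap[n.parent],
            )
            for n in tree
        )
        assert total_cable_length(rotated) == pytest.approx(total_cable_length(tree), rel=1e-9)


class TestConvexHull:
    def test_box_corners(self):
        corners = np.array(
            [[x, y, z] for x in (0, 10) for y in (0, 20) for z in (0, 30)], float
        )
        h = convex_hull_metrics(corners)
        assert h.volume == pytest.approx(6000.0)
        assert (h.x_width, h.y_width, h.z_height) == (10.0, 20.0, 30.0)

    def test_colinear_points_volume_zero(self):
        pts = np.array([[t, 2 * t, 3 * t] for t in range(5)], float)
        h = convex_hull_metrics(pts)
        assert h.volume == 0.0
        assert h.x_width == pytest.approx(4.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_metrics(np.empty((0, 3)))

    def test_volume_against_rejection_sampling_oracle(self, rng):
        pts = rng.normal(size=(500, 3)) * [5, 8, 3]
        h = convex_hull_metrics(pts)
        from scipy.spatial import Delaunay

        lo, hi = pts.min(axis=0), pts.max(axis=0)
        samples = rng.uniform(lo, hi, size=(200_000, 3))
        inside = Delaunay(pts).find_simplex(samples) >= 0
        mc_volume = inside.mean() * np.prod(hi - lo)
        assert h.volume == pytest.approx(mc_volume, rel=0.02)

    def test_monotone_under_adding_points(self, rng):
        pts = rng.normal(size=(60, 3))
        vol_small = convex_hull_metrics(pts[:30]).volume
        vol_full = convex_hull_metrics(pts).volume
        assert vol_full >= vol_small

    def test_skeleton_hull_within_mask_hull(self, phantom_params):
        tree = make_arbor_skeleton(2, 4)
        mask = rasterize_tree(tree, phantom_params)
        assert (
            convex_hull_metrics(tree.positions()).volume
            <= convex_hull_metrics(mask).volume
        )


class TestTerminalBranches:
    def test_unbranched_arbor_single_branch(self):
        tree = _path_tree([(0, 0, 0), (0, 0, 10), (0, 0, 20)])
        assert len(enumerate_terminal_branches(tree)) == 1

    def test_full_binary_tree_four_leaves(self):
        tree = make_arbor_skeleton(1, 4)
        assert len(enumerate_terminal_branches(tree, min_length_um=0.0)) == 4

    def test_short_spur_not_counted(self):
        # main path plus a 1 μm spur off an interior node; min length 2 μm
        nodes = [SkeletonNode(1, np.array([0.0, 0, 0]), 0.5, None)]
        for k in range(2, 12):
            nodes.append(SkeletonNode(k, np.array([0.0, 0, k - 1.0]), 0.5, k - 1))
        nodes.append(SkeletonNode(99, np.array([1.0, 0, 5.0]), 0.5, 6))
        tree = SkeletonTree(nodes)
        assert len(enumerate_terminal_branches(tree, min_length_um=2.0)) == 1
        assert len(enumerate_terminal_branches(tree, min_length_um=0.0)) == 2

    def test_count_equals_leaf_count_at_zero_floor(self):
        for seed in range(4):
            tree = make_arbor_skeleton(seed, 2 + seed)
            assert len(enumerate_terminal_branches(tree, 0.0)) == len(tree.leaves())


class TestWidthsAndSwellings:
    def test_uniform_tube_profile(self):
        # finer pitch than the acquisition default so the 1 μm tube is
        # rasterized with several voxels across its calibre
        fine = ImagingParams(
            field_xy_um=12.0, pixels_xy=96, z_step_um=0.25, depth_um=8.0,
            background_level=0.0, noise_model=("none", {}),
        )
        pts = [(1.0 + t, 6.0, 4.0) for t in np.arange(0.0, 10.5, 0.5)]
        tree = _path_tree(pts, radius=0.5)
        mask = rasterize_tree(tree, fine)
        branch = enumerate_terminal_branches(tree, 0.0)[0]
        prof = branch_width_profile(branch, mask)
        assert prof.baseline_um == pytest.approx(1.0, abs=0.3)
        assert np.all(np.diff(prof.arc_um) > 0)

    def test_terminal_sphere_by_construction(self, phantom_params):
        """Tube of diameter 1 μm ending in a 3.5 μm sphere: max/baseline ≥ 3."""
        pts = [(5.0 + t, 15.0, 20.0) for t in np.arange(0.0, 15.5, 0.5)]
        nodes = [SkeletonNode(1, np.asarray(pts[0]), 0.5, None)]
        for k, p in enumerate(pts[1:], start=2):
            nodes.append(SkeletonNode(k, np.asarray(p), 0.5, k - 1))
        nodes.append(SkeletonNode(len(nodes) + 1, np.array([21.0, 15.0, 20.0]), 1.75, len(nodes)))
        tree = SkeletonTree(nodes)
        mask = rasterize_tree(tree, phantom_params)
        branch = enumerate_terminal_branches(tree, 0.0)[0]
        prof = branch_width_profile(branch, mask)
        assert prof.diameter_um.max() / prof.baseline_um >= 3.0

    def test_branch_outside_mask_rejected(self, phantom_params):
        pts = [(5.0 + t, 15.0, 20.0) for t in np.arange(0.0, 10.5, 0.5)]
        tree = _path_tree(pts)
        other = rasterize_tree(_path_tree([(5.0, 25.0, 10.0), (15.0, 25.0, 10.0)]), phantom_params)
        branch = enumerate_terminal_branches(tree, 0.0)[0]
        with pytest.raises(ValueError, match="mask"):
            branch_width_profile(branch, other)

    @pytest.mark.parametrize(
        "ratio,expected",
        [(3.5, True), (2.9, False), (3.0, True)],  # "at least 3×" is inclusive
    )
    def test_swelling_rule_threshold(self, ratio, expected):
        arc = np.linspace(0, 10, 21)
        diam = np.full_like(arc, 1.0)
        diam[-1] = ratio
        from arbortrack.morphometry import WidthProfile

        prof = WidthProfile(arc, diam, baseline_um=1.0)
        ann = detect_swellings(prof)
        assert ann.is_swelling is expected
        if expected:
            assert ann.location == "tip"
            assert ann.width_ratio == pytest.approx(ratio)

    def test_shaft_swelling_location(self):
        arc = np.linspace(0, 10, 21)
        diam = np.full_like(arc, 1.0)
        diam[8] = 3.6  # 40% along the arc
        from arbortrack.morphometry import WidthProfile

        ann = detect_swellings(WidthProfile(arc, diam, 1.0))
        assert ann.is_swelling and ann.location == "shaft"

    def test_tree_width_profile_uses_node_radii(self):
        tree = _path_tree([(0, 0, 0), (0, 0, 5), (0, 0, 10)], radius=0.4)
        branch = enumerate_terminal_branches(tree, 0.0)[0]
        prof = tree_width_profile(branch)
        np.testing.assert_allclose(prof.diameter_um, 0.8)
        assert prof.baseline_um == pytest.approx(0.8)
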