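import numpy as np
import pytest

from vasculometry import (PhantomSpec, ROI, bifurcation_angles, build_graph,
                          diameter_coded_volume, diameter_distribution,
                          euclidean_distance_map, generate_tree,
                          ground_truth_mask, radius_from_edm, rasterize_tree,
                          side_branch_tree, summarize_roi, thinning_3d,
                          vessel_volume)
from vasculometry.segmentation import BinaryMask
from vasculometry.skeletonization import RadiusMap, Skeleton
from vasculometry.vessel_graph import (ENDPOINT, JUNCTION, SLAB,
                                       classify_skeleton_voxels)

S = 3.7


def skeleton_from(voxels, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    m = np.zeros(shape, bool)
    for v in voxels:
        m[v] = True
    return Skeleton(m, spacing)


def graph_of_mask(mask: BinaryMask):
    skel = thinning_3d(mask)
    edm = euclidean_distance_map(mask)
    return build_graph(skel, radius_from_edm(skel, edm))


class TestClassify:
    def test_straight_path(self):
        skel = skeleton_from([(5, 5, z) for z in range(3, 13)])
        labels = classify_skeleton_voxels(skel)
        assert (labels == ENDPOINT).sum() == 2
        assert (labels == SLAB).sum() == 8
        assert (labels == JUNCTION).sum() == 0

    def test_y_shape_single_junction_voxel(self):
        arms = [(8, 8, 8)]
        arms += [(8, 8, 8 - d) for d in range(1, 5)]
        arms += [(8 + d, 8, 8 + d) for d in range(1, 5)]
        arms += [(8 - d, 8, 8 + d) for d in range(1, 5)]
        labels = classify_skeleton_voxels(skeleton_from(arms))
        assert (labels == ENDPOINT).sum() == 3
        assert (labels == JUNCTION).sum() == 1

    def test_isolated_voxel_is_endpoint(self):
        labels = classify_skeleton_voxels(skeleton_from([(4, 4, 4)]))
        assert (labels == ENDPOINT).sum() == 1


class TestBuildGraph:
    def test_y_skeleton_three_segments_one_junction(self):
        arms = [(8, 8, 8)]
        arms += [(8, 8, 8 - d) for d in range(1, 6)]
        arms += [(8 + d, 8, 8 + d) for d in range(1, 6)]
        arms += [(8 - d, 8, 8 + d) for d in range(1, 6)]
        g = build_graph(skeleton_from(arms), None)
        assert g.vn == 3
        assert g.vnn == 1

    def test_binary_tree_phantom_recovered_exactly(self):
        spec = PhantomSpec(noise_sigma=0.0, blur_sigma_um=0.0)
        truth = generate_tree(spec)
        vol = rasterize_tree(truth, spec)
        mask = BinaryMask(ground_truth_mask(vol, spec), spec.voxel_spacing_um)
        g = graph_of_mask(mask)
        assert g.vn == truth.n_segments == 7
        assert g.vnn == truth.n_bifurcations == 3

    def test_closed_loop_flagged_cyclic(self):
        # diamond-shaped loop: every voxel has exactly two 26-neighbours
        r = 6
        ring = {(8 + dx, 8 + dy, 8)
                for dx in range(-r, r + 1)
                for dy in (r - abs(dx), abs(dx) - r)}
        g = build_graph(skeleton_from(sorted(ring)), None)
        assert g.vn == 1
        assert g.vnn == 0
        assert g.cyclic
        assert g.segments[0].is_cycle

    def test_two_voxel_component_is_one_segment(self):
        g = build_graph(skeleton_from([(2, 2, 2), (2, 2, 3)]), None)
        assert g.vn == 1
        assert {n.kind for n in g.nodes} == {"endpoint"}

    def test_segment_length_is_physical(self):
        skel = skeleton_from([(5, 5, z) for z in range(3, 13)],
                             spacing=(1.0, 1.0, 2.0))
        g = build_graph(skel, None)
        assert g.segments[0].length_um == pytest.approx(9 * 2.0)


class TestVesselVolume:
    def test_full_roi_fraction_one(self):
        mask = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        frac, _ = vessel_volume(mask)
        assert frac == 1.0

    def test_empty_mask(self):
        frac, mm3 = vessel_volume(BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))
        assert frac == 0.0 and mm3 == 0.0

    def test_physical_units(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:100] = True
        _, mm3 = vessel_volume(BinaryMask(m, (3.7, 3.7, 3.7)))
        assert mm3 == pytest.approx(100 * 3.7**3 * 1e-9)  # 5.0653e-6 mm^3

    def test_roi_restriction(self):
        m = np.zeros((8, 8, 8), bool)
        m[:, :, :4] = True
        frac, _ = vessel_volume(BinaryMask(m, (1, 1, 1)), ROI((0, 0, 0), (8, 8, 2)))
        assert frac == 1.0
        frac, _ = vessel_volume(BinaryMask(m, (1, 1, 1)), ROI((0, 0, 4), (8, 8, 8)))
        assert frac == 0.0


class TestDiameterDistribution:
    def test_half_open_binning(self):
        skel = skeleton_from([(5, 5, z) for z in range(3, 13)])
        radii = RadiusMap(np.where(skel.data, 10.0, 0.0), skel.spacing_um)
        g = build_graph(skel, radii)
        assert g.segments[0].diameter_um == pytest.approx(20.0)
        edges, counts = diameter_distribution(g, [0, 10, 20, 30])
        assert counts.tolist() == [0, 0, 1]

    def test_empty_graph(self):
        g = build_graph(skeleton_from([(4, 4, 4)]), None)
        _, counts = diameter_distribution(g, [0, 10, 20])
        assert counts.sum() == 0

    def test_counts_conserve_vn(self):
        spec = PhantomSpec(noise_sigma=0.0, blur_sigma_um=0.0)
        vol = rasterize_tree(generate_tree(spec), spec)
        mask = BinaryMask(ground_truth_mask(vol, spec), spec.voxel_spacing_um)
        g = graph_of_mask(mask)
        report = summarize_roi(mask, g)
        assert report.histogram_counts.sum() == report.vn


class TestBifurcationAngles:
    @pytest.mark.parametrize("theta", [30.0, 60.0, 90.0])
    def test_side_branch_recovered(self, theta):
        spec = PhantomSpec(grid_shape=(96, 96, 96), trunk_radius_um=3 * S,
                           trunk_span_frac=(0.1, 0.9), noise_sigma=0.0,
                           blur_sigma_um=0.0)
        truth = side_branch_tree(spec, theta, branch_radius_um=2 * S,
                                 branch_length_um=150.0)
        vol = rasterize_tree(truth, spec)
        mask = BinaryMask(ground_truth_mask(vol, spec), spec.voxel_spacing_um)
        g = graph_of_mask(mask)
        angles = [a["theta_deg"] for a in bifurcation_angles(g)]
        assert min(abs(a - theta) for a in angles) <= 5.0

    def test_caudal_branch_negative(self):
        spec = PhantomSpec(grid_shape=(96, 96, 96), trunk_radius_um=3 * S,
                           trunk_span_frac=(0.1, 0.9), noise_sigma=0.0,
                           blur_sigma_um=0.0)
        truth = side_branch_tree(spec, 135.0, branch_radius_um=2 * S,
                                 branch_length_um=150.0)
        (branch,) = [s for s in truth.segments if s.level == 1]
        assert branch.angle_to_trunk_deg == pytest.approx(-45.0)
        vol = rasterize_tree(truth, spec)
        mask = BinaryMask(ground_truth_mask(vol, spec), spec.voxel_spacing_um)
        g = graph_of_mask(mask)
        angles = [a["theta_deg"] for a in bifurcation_angles(g)]
        assert min(abs(a + 45.0) for a in angles) <= 5.0

    def test_short_branch_omitted(self):
        arms = [(8, 8, 8)]
        arms += [(8, 8, 8 - d) for d in range(1, 6)]
        arms += [(8 + d, 8, 8 + d) for d in range(1, 6)]
        arms += [(8 - d, 8, 8 + d) for d in range(1, 3)]  # 2-voxel stub
        g = build_graph(skeleton_from(arms), None)
        angles = bifurcation_angles(g, min_branch_voxels=5)
        stub_segs = [s.id for s in g.segments if len(s.polyline_voxels) <= 3]
        assert all(a["segment_id"] not in stub_segs for a in angles)


class TestSummarizeRoi:
    def test_empty_mask_all_zero(self):
        mask = BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1))
        g = build_graph(skeleton_from([], shape=(8, 8, 8)), None)
        report = summarize_roi(mask, g)
        assert report.vn == 0 and report.vnn == 0
        assert report.vv_fraction == 0.0
        assert report.histogram_counts.sum() == 0
        assert len(report.segment_table) == 0

    def test_segment_touching_roi_counted(self):
        skel = skeleton_from([(5, 5, z) for z in range(2, 14)])
        mask = BinaryMask(skel.data.copy(), (1, 1, 1))
        radii = RadiusMap(np.where(skel.data, 1.0, 0.0), (1, 1, 1))
        g = build_graph(skel, radii)
        report = summarize_roi(mask, g, roi=ROI((0, 0, 0), (16, 16, 5)))
        assert report.vn == 1  # crosses the boundary but is counted

    def test_metrics_keys(self):
        mask = BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1))
        g = build_graph(skeleton_from([], shape=(8, 8, 8)), None)
        m = summarize_roi(mask, g).metrics()
        assert set(m) == {"VV_fraction", "VV_mm3", "VN", "VNN", "VD_mean_um"}


def test_diameter_coded_volume_labels_skeleton():
    skel = skeleton_from([(5, 5, z) for z in range(3, 13)])
    radii = RadiusMap(np.where(skel.data, 7.0, 0.0), skel.spacing_um)
    g = build_graph(skel, radii)
    coded = diameter_coded_volume(g, skel.data.shape)
    assert np.all(coded[skel.data] == pytest.approx(14.0))
    assert np.all(coded[~skel.data] == 0)
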