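import json

import numpy as np
import pytest

from vasculometry import (InjurySpec, PhantomSpec, apply_injury, degrade_volume,
                          generate_tree, ground_truth_mask, rasterize_tree,
                          side_branch_tree, signed_angle_to_trunk)
from vasculometry.phantom import GroundTruthGraph

S = 3.7


def small_spec(**kw):
    defaults = dict(grid_shape=(64, 64, 64), trunk_radius_um=4 * S,
                    branch_levels=1, noise_sigma=0.0, blur_sigma_um=0.0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestGenerateTree:
    @pytest.mark.parametrize("levels,n_segments,n_bifurcations", [
        (0, 1, 0),       # degenerate: a single trunk
        (1, 3, 1),
        (2, 7, 3),       # complete binary tree: 1 + 2 + 4
    ])
    def test_complete_binary_tree_counts(self, levels, n_segments, n_bifurcations):
        spec = PhantomSpec(branch_levels=levels)
        g = generate_tree(spec)
        assert g.n_segments == n_segments
        assert g.n_bifurcations == n_bifurcations
        assert g.n_endpoints == n_segments - n_bifurcations + 1

    def test_deterministic_for_fixed_seed(self):
        a = generate_tree(PhantomSpec(rng_seed=42)).to_json_dict()
        b = generate_tree(PhantomSpec(rng_seed=42)).to_json_dict()
        assert json.dumps(a) == json.dumps(b)
        c = generate_tree(PhantomSpec(rng_seed=43)).to_json_dict()
        assert json.dumps(a) != json.dumps(c)

    def test_branch_angles_match_spec_up_to_jitter(self):
        spec = PhantomSpec(branch_angle_deg=60.0, jitter_deg=5.0)
        g = generate_tree(spec)
        for seg in g.segments:
            if seg.level == 1:
                assert abs(seg.angle_to_trunk_deg - 60.0) <= 5.0 + 1e-9

    def test_taper_below_voxel_rejected_naming_level(self):
        spec = PhantomSpec(trunk_radius_um=7.4, taper_ratio=0.5, branch_levels=2,
                           radius_range_um=(3.7, 50.0))
        # level 1: 3.7 (ok), level 2: 1.85 < one voxel
        with pytest.raises(ValueError, match="level 2"):
            generate_tree(spec)

    def test_segment_arc_length_consistent(self):
        g = generate_tree(PhantomSpec())
        for seg in g.segments:
            chord = np.linalg.norm(seg.polyline_um[-1] - seg.polyline_um[0])
            assert seg.length_um == pytest.approx(chord, abs=1e-6)

    def test_tree_is_connected_and_acyclic(self):
        import networkx as nx

        g = generate_tree(PhantomSpec())
        nxg = g.to_networkx()
        assert nx.is_connected(nxg)
        assert nx.number_of_edges(nxg) == nx.number_of_nodes(nxg) - 1


class TestSignedAngle:
    @pytest.mark.parametrize("direction,expected", [
        ((1.0, 0.0, 0.0), 90.0),                  # perpendicular
        ((1.0, 0.0, 1.0), 45.0),                  # rostral-leaning
        ((1.0, 0.0, -1.0), -45.0),                # caudal mirror
        ((0.0, 0.0, 1.0), 0.0),
        ((0.0, 0.0, -1.0), -0.0),
    ])
    def test_convention(self, direction, expected):
        assert signed_angle_to_trunk(direction) == pytest.approx(expected, abs=1e-9)


class TestRasterize:
    def test_slicewise_disc_matches_brute_force(self):
        spec = small_spec(branch_levels=0, trunk_radius_um=5 * S,
                          trunk_span_frac=(0.15, 0.85))
        g = generate_tree(spec)
        vol = rasterize_tree(g, spec)
        mask = ground_truth_mask(vol, spec)
        (seg,) = g.segments
        z0, z1 = seg.polyline_um[0][2], seg.polyline_um[1][2]
        cx, cy = seg.polyline_um[0][:2]
        xs = np.arange(64) * S
        for z_idx in range(64):
            z = z_idx * S
            dx = xs[:, None] - cx
            dy = xs[None, :] - cy
            lateral2 = dx**2 + dy**2
            dz = max(z0 - z, 0.0, z - z1)
            expected = lateral2 + dz**2 < (5 * S) ** 2
            np.testing.assert_array_equal(mask[:, :, z_idx], expected)

    def test_empty_graph_is_pure_background(self):
        spec = small_spec()
        vol = rasterize_tree(GroundTruthGraph(), spec)
        assert np.all(vol.data == spec.background_intensity)

    def test_radius_one_voxel_tube_is_connected(self):
        from vasculometry.segmentation import connected_components

        spec = small_spec(branch_levels=0, trunk_radius_um=S,
                          trunk_span_frac=(0.2, 0.8))
        vol = rasterize_tree(generate_tree(spec), spec)
        mask = ground_truth_mask(vol, spec)
        assert mask.sum() > 0
        _, sizes = connected_components(mask, 26)
        assert len(sizes) == 1

    def test_tube_exiting_grid_names_segment(self):
        spec = small_spec(branch_levels=0, trunk_radius_um=10 * S,
                          trunk_span_frac=(0.0, 1.0))
        g = generate_tree(spec)
        with pytest.raises(ValueError, match="segment 0"):
            rasterize_tree(g, spec)


class TestDegrade:
    def test_identity_when_disabled(self):
        spec = small_spec(noise_sigma=0.0, blur_sigma_um=0.0)
        vol = rasterize_tree(generate_tree(spec), spec)
        out = degrade_volume(vol, spec)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_deterministic_noise(self):
        spec = small_spec(noise_sigma=10.0, blur_sigma_um=2.0, rng_seed=5)
        vol = rasterize_tree(generate_tree(spec), spec)
        a = degrade_volume(vol, spec)
        b = degrade_volume(vol, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_blur_conserves_mean(self):
        spec = small_spec(noise_sigma=0.0, blur_sigma_um=5.0)
        vol = rasterize_tree(generate_tree(spec), spec)
        out = degrade_volume(vol, spec)
        assert out.data.mean() == pytest.approx(vol.data.mean(), rel=1e-6)


class TestInjury:
    @staticmethod
    def _phantom():
        spec = PhantomSpec(noise_sigma=0.0, blur_sigma_um=0.0)
        g = generate_tree(spec)
        return spec, g, rasterize_tree(g, spec)

    def test_null_injury_is_identity(self):
        spec, g, vol = self._phantom()
        g2, vol2 = apply_injury(g, vol, InjurySpec(epicenter_um=(100, 100, 100)), spec)
        assert g2 is g
        np.testing.assert_array_equal(vol2.data, vol.data)

    def test_enclosing_cavity_removes_enclosed_segments(self):
        spec, g, vol = self._phantom()
        # count segments whose sampled polylines fall inside the cavity
        bif = [n for n in g.nodes if n.kind == "bifurcation"][1]
        injury = InjurySpec(epicenter_um=tuple(bif.position_um),
                            cavity_semiaxes_um=(90.0, 90.0, 140.0))
        from vasculometry.phantom import _densify, _inside_cavity

        fully_inside = 0
        for s in g.segments:
            samples, _ = _densify(s.polyline_um, step=S / 2)
            if _inside_cavity(samples, injury).all():
                fully_inside += 1
        assert fully_inside >= 2
        g2, _ = apply_injury(g, vol, injury, spec)
        assert g.n_segments - g2.n_segments == fully_inside

    def test_growing_cavity_never_regrows_vessel(self):
        spec, g, vol = self._phantom()
        center = tuple(np.asarray(spec.physical_extent_um()) / 2)
        prev = None
        for scale in (0.0, 40.0, 80.0, 160.0):
            injury = InjurySpec(epicenter_um=center,
                                cavity_semiaxes_um=(scale, scale, 1.5 * scale))
            _, vol2 = apply_injury(g, vol, injury, spec)
            fg = int(ground_truth_mask(vol2, spec).sum())
            if prev is not None:
                assert fg <= prev
            prev = fg

    def test_cavity_covering_grid_rejected(self):
        spec, g, vol = self._phantom()
        extent = spec.physical_extent_um()
        with pytest.raises(ValueError, match="whole grid"):
            apply_injury(g, vol, InjurySpec(
                epicenter_um=tuple(extent / 2),
                cavity_semiaxes_um=(2e4, 2e4, 2e4)), spec)

    def test_tilt_moves_angles_away_rostral_and_caudal(self):
        spec, g, vol = self._phantom()
        bifs = [n for n in g.nodes if n.kind == "bifurcation"]
        ez = bifs[0].position_um[2] + 40.0  # just rostral of the trunk junction
        injury = InjurySpec(epicenter_um=(bifs[0].position_um[0],
                                          bifs[0].position_um[1], ez),
                            tilt_deg=15.0, tilt_extent_um=300.0)
        g2, _ = apply_injury(g, vol, injury, spec)
        before = {s.id: s.angle_to_trunk_deg for s in g.segments if s.level == 1}
        after = {s.id: s.angle_to_trunk_deg for s in g2.segments if s.level == 1}
        for sid, theta0 in before.items():
            # trunk junction is caudal of the epicenter: tilt toward caudal,
            # i.e. the angle to +z grows by 15 degrees
            assert after[sid] == pytest.approx(theta0 + 15.0, abs=1e-6)

    def test_spindle_shape_invariant(self):
        with pytest.raises(ValueError, match="spindle"):
            InjurySpec(epicenter_um=(0, 0, 0), cavity_semiaxes_um=(50, 50, 30))


class TestSideBranchTree:
    def test_branch_angle_is_exact(self):
        spec = PhantomSpec(grid_shape=(96, 96, 96), trunk_radius_um=3 * S,
                           noise_sigma=0.0)
        for theta in (30.0, 60.0, 90.0):
            g = side_branch_tree(spec, theta)
            (branch,) = [s for s in g.segments if s.level == 1]
            assert branch.angle_to_trunk_deg == pytest.approx(theta, abs=1e-9)
        assert g.n_bifurcations == 1
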