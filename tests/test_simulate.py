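import math

import numpy as np
import pytest
from skimage import draw as skdraw

from phytoscreen.simulate import (
    PRESET_NAMES,
    RootSystem,
    Segment,
    WellGeometry,
    phenotype_preset,
    render_rosette,
    render_side_view,
    render_strip,
    simulate_root_system,
)


class TestGrowth:
    def test_straight_vertical_limit(self):
        """No tortuosity and full gravitropism give a plumb-line primary."""
        params = phenotype_preset(
            "control", tortuosity=0.0, gravitropism=1.0,
            lateral_density=0.0, hair_density=0.0, n_plants=1,
        )
        system = simulate_root_system(params, WellGeometry(), seed=5)
        assert len(system.segments) == 1
        pts = system.segments[0].points
        assert np.allclose(pts[:, 1], pts[0, 1])  # no sideways drift
        expected = params.primary_rate * params.days
        assert system.total_length() == pytest.approx(expected, abs=1.0)

    def test_no_laterals_no_hairs_single_segment_per_plant(self):
        params = phenotype_preset("control", lateral_density=0.0, hair_density=0.0)
        system = simulate_root_system(params, WellGeometry(), seed=5)
        assert len(system.segments) == params.n_plants
        assert {s.kind for s in system.segments} == {"primary"}

    def test_fixed_seed_reproducible(self):
        params = phenotype_preset("control")
        a = simulate_root_system(params, WellGeometry(), seed=11)
        b = simulate_root_system(params, WellGeometry(), seed=11)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.points, sb.points)

    def test_root_stays_inside_well(self):
        geom = WellGeometry()
        system = simulate_root_system(
            phenotype_preset("agravitropic_wavy"), geom, seed=3
        )
        for seg in system.segments:
            assert seg.points[:, 0].min() >= 0
            assert seg.points[:, 0].max() <= geom.height_px - 1
            assert seg.points[:, 1].min() >= 0
            assert seg.points[:, 1].max() <= geom.width_px - 1

    def test_degenerate_params_give_empty_system(self):
        params = phenotype_preset("control", days=0.0, n_plants=0)
        system = simulate_root_system(params, WellGeometry(), seed=1)
        assert system.segments == []


class TestPresets:
    def test_known_names_and_unknown_rejected(self):
        for name in PRESET_NAMES:
            phenotype_preset(name)
        with pytest.raises(ValueError, match="unknown preset"):
            phenotype_preset("hyper_growth")

    def test_no_laterals_definition(self):
        assert phenotype_preset("no_laterals").lateral_density == 0.0

    def test_short_primary_halves_rendered_root_length(self):
        geom = WellGeometry()
        masses = {}
        for name in ("control", "short_primary"):
            params = phenotype_preset(name, lateral_density=0.0, hair_density=0.0)
            total = 0.0
            for seed in range(4):
                system = simulate_root_system(params, geom, seed=seed)
                total += render_side_view(system, noise_sd=0.0).truth_probability.sum()
            masses[name] = total
        assert masses["control"] / masses["short_primary"] > 2.0

    def test_agravitropic_track_deviates_from_vertical(self):
        """More than half the wavy primary runs >22.5 degrees off plumb."""
        params = phenotype_preset("agravitropic_wavy", n_plants=1,
                                  lateral_density=0.0, hair_density=0.0)
        deviant = total = 0
        for seed in range(4):
            system = simulate_root_system(params, WellGeometry(), seed=seed)
            d = np.diff(system.segments[0].points, axis=0)
            angles = np.degrees(np.arctan2(np.abs(d[:, 1]), np.abs(d[:, 0])))
            deviant += (angles > 22.5).sum()
            total += len(angles)
        assert deviant / total > 0.5


class TestSideRendering:
    def test_empty_system_renders_pure_background(self):
        geom = WellGeometry(height_px=80, width_px=40)
        rendered = render_side_view(RootSystem([], geom), noise_sd=0.0)
        assert rendered.truth_probability.sum() == 0.0
        assert not rendered.truth_orientation.valid.any()
        assert np.ptp(rendered.image) == 0.0

    def test_horizontal_bar_coverage_counts_stroke_pixels(self):
        geom = WellGeometry(height_px=60, width_px=220)
        bar = RootSystem(
            [Segment(np.array([[30.0, 10.0], [30.0, 210.0]]), "primary", 1.0)], geom
        )
        rendered = render_side_view(bar, noise_sd=0.0, blur_sigma=0.0)
        assert rendered.truth_probability.sum() == pytest.approx(200.0)
        valid = rendered.truth_orientation.valid
        assert np.all(rendered.truth_orientation.angle_deg[valid] == 0.0)

    def test_vertical_bar_orientation_is_90(self):
        geom = WellGeometry(height_px=220, width_px=60)
        bar = RootSystem(
            [Segment(np.array([[10.0, 30.0], [210.0, 30.0]]), "primary", 1.0)], geom
        )
        rendered = render_side_view(bar, noise_sd=0.0, blur_sigma=0.0)
        valid = rendered.truth_orientation.valid
        assert np.all(rendered.truth_orientation.angle_deg[valid] == 90.0)

    def test_truth_unaffected_by_blur_and_noise(self):
        """Ground truth is computed before imaging degradation."""
        geom = WellGeometry(height_px=120, width_px=40)
        system = simulate_root_system(
            phenotype_preset("control", days=3.0), geom, seed=9
        )
        clean = render_side_view(system, noise_sd=0.0, blur_sigma=0.0)
        degraded = render_side_view(system, noise_sd=0.05, blur_sigma=1.2, seed=1)
        assert np.array_equal(clean.truth_probability, degraded.truth_probability)
        assert np.array_equal(
            clean.truth_orientation.valid, degraded.truth_orientation.valid
        )

    def test_seed_determinism_bit_identical(self):
        geom = WellGeometry(height_px=120, width_px=40)
        system = simulate_root_system(phenotype_preset("control", days=3.0), geom, seed=2)
        a = render_side_view(system, noise_sd=0.03, seed=4)
        b = render_side_view(system, noise_sd=0.03, seed=4)
        assert np.array_equal(a.image, b.image)

    def test_mirror_image_has_identical_folded_orientations(self):
        geom = WellGeometry(height_px=100, width_px=100)
        theta = math.radians(30)
        p0 = [50 - 30 * math.sin(theta), 50 - 30 * math.cos(theta)]
        p1 = [50 + 30 * math.sin(theta), 50 + 30 * math.cos(theta)]
        bar = RootSystem([Segment(np.array([p0, p1]), "lateral", 2.0)], geom)
        mirrored = RootSystem(
            [Segment(np.array([[r, 99.0 - c] for r, c in (p0, p1)]), "lateral", 2.0)],
            geom,
        )
        a = render_side_view(bar, noise_sd=0.0)
        b = render_side_view(mirrored, noise_sd=0.0)
        va, vb = a.truth_orientation.valid, b.truth_orientation.valid
        assert np.allclose(
            np.sort(a.truth_orientation.angle_deg[va]),
            np.sort(b.truth_orientation.angle_deg[vb]),
        )

    def test_orientation_range_and_probability_range(self, control_well):
        prob = control_well.truth_probability
        orient = control_well.truth_orientation
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        angles = orient.angle_deg[orient.valid]
        assert angles.min() >= 0.0 and angles.max() <= 90.0


class TestRosette:
    def test_zero_leaves_is_all_white(self):
        rendered = render_rosette(0, 10.0, hue=120.0, noise_sd=0.0)
        assert not rendered.truth_shoot_mask.any()
        assert np.all(rendered.image == 1.0)

    def test_single_leaf_matches_rasterised_ellipse(self):
        geom = WellGeometry(top_view_px=120)
        leaf_size = 14.0
        rendered = render_rosette(1, leaf_size, hue=110.0, geometry=geom, noise_sd=0.0)
        centre = (120 - 1) / 2.0
        rr, cc = skdraw.ellipse(
            centre, centre + 0.75 * leaf_size, 0.45 * leaf_size, leaf_size,
            shape=(120, 120), rotation=0.0,
        )
        expected = np.zeros((120, 120), dtype=bool)
        expected[rr, cc] = True
        assert np.array_equal(rendered.truth_shoot_mask, expected)

    def test_pure_green_leaves_are_pure_green_pixels(self):
        rendered = render_rosette(
            4, 10.0, hue=120.0, saturation=1.0, value=1.0, noise_sd=0.0
        )
        mask = rendered.truth_shoot_mask
        assert mask.any()
        assert np.allclose(rendered.image[mask], [0.0, 1.0, 0.0])

    def test_overlap_uses_union_not_sum(self):
        dense = render_rosette(8, 20.0, hue=110.0, noise_sd=0.0)
        assert dense.truth_shoot_mask.sum() <= dense.truth_shoot_mask.size

    def test_hue_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            render_rosette(1, 5.0, hue=400.0)


class TestStripComposition:
    def test_crops_recover_wells_exactly(self, small_geometry):
        wells = [
            render_side_view(
                simulate_root_system(
                    phenotype_preset("control", days=3.0), small_geometry, seed=s
                ),
                noise_sd=0.0,
            )
            for s in range(3)
        ]
        strip, boxes = render_strip(wells)
        for well, (r0, c0, r1, c1) in zip(wells, boxes):
            assert np.array_equal(strip[r0:r1, c0:c1], well.image)

    def test_empty_strip_rejected(self):
        with pytest.raises(ValueError):
            render_strip([])
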