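"""OCT-A network: cleaning, skeleton radii, segments, sectors, density."""

import numpy as np
import pandas as pd
import pytest

from cyclovasc import octa
from cyclovasc.synthetic import TreeSpec, gen_retina_image, render_segments


def straight_vessel_df(radius_um, length_um=500.0, y_um=0.0, x0_um=None):
    if x0_um is None:
        x0_um = -length_um / 2.0
    return pd.DataFrame([{
        "y0": y_um, "x0": x0_um, "y1": y_um, "x1": x0_um + length_um,
        "length_um": length_um, "radius_um": radius_um}])


class TestCleanMask:
    @staticmethod
    def blob(size, offset, canvas):
        # size-pixel 8-connected square-ish cluster at offset
        side = int(np.ceil(np.sqrt(size)))
        placed = 0
        for i in range(side):
            for j in range(side):
                if placed < size:
                    canvas[offset[0] + i, offset[1] + j] = True
                    placed += 1
        return canvas

    def test_threshold_is_strictly_below_30(self):
        canvas = np.zeros((60, 60), bool)
        canvas = self.blob(29, (5, 5), canvas)
        canvas = self.blob(30, (5, 30), canvas)
        canvas = self.blob(35, (35, 5), canvas)
        out = octa.clean_mask(canvas)
        assert out.sum() == 65          # 29-px cluster gone, 30 and 35 kept
        assert not out[5:12, 5:12].any()

    def test_empty_mask_stays_empty(self):
        assert octa.clean_mask(np.zeros((10, 10), bool)).sum() == 0


class TestSkeletonGraph:
    def test_bar_width9_centreline_radius(self):
        # horizontal bar 9 px wide: centreline radius ~4.5 px away from ends
        mask = np.zeros((30, 60), np.uint8)
        mask[10:19, 5:55] = 1
        angio = octa.BinaryAngiogram(mask=mask, pixel_pitch=2.0)
        skel = octa.skeletonize_and_graph(angio)
        mid_radii = [d["radius_um"] for (y, x), d in skel.graph.nodes(data=True)
                     if 20 <= x <= 40]
        assert np.allclose(mid_radii, 4.5 * 2.0, atol=0.5 * 2.0)
        assert np.median(mid_radii) == pytest.approx(9.0, abs=1e-9)

    def test_node_count_equals_skeleton_pixels(self):
        from skimage.morphology import skeletonize
        angio, _ = gen_retina_image(seed=1)
        cleaned = octa.clean_mask(angio.mask)
        skel = octa.skeletonize_and_graph(octa.BinaryAngiogram(
            mask=cleaned.astype(np.uint8), pixel_pitch=angio.pixel_pitch))
        assert skel.n_nodes == int(skeletonize(cleaned).sum())

    def test_empty_mask_gives_empty_graph(self):
        angio = octa.BinaryAngiogram(mask=np.zeros((10, 10), np.uint8),
                                     pixel_pitch=9.375)
        assert octa.skeletonize_and_graph(angio).n_nodes == 0

    def test_solid_blob_graph_has_no_cycles(self):
        import networkx as nx
        mask = np.zeros((40, 40), np.uint8)
        mask[10:30, 10:30] = 1           # solid square, no holes
        skel = octa.skeletonize_and_graph(
            octa.BinaryAngiogram(mask=mask, pixel_pitch=1.0))
        assert skel.n_nodes >= 1
        g = skel.graph
        assert g.number_of_edges() <= g.number_of_nodes() - 1 or \
            len(nx.cycle_basis(g)) == 0


class TestSegments:
    def test_straight_path_single_segment_with_length(self):
        # 101-node one-pixel horizontal path -> one segment of 100 steps
        mask = np.zeros((20, 120), np.uint8)
        mask[10, 5:106] = 1
        skel = octa.skeletonize_and_graph(
            octa.BinaryAngiogram(mask=mask, pixel_pitch=2.0))
        segments = octa.extract_segments(skel)
        assert len(segments) == 1
        assert len(segments[0].path) == 101
        assert segments[0].length_um == pytest.approx(100 * 2.0)

    def test_y_junction_gives_three_segments(self):
        mask = np.zeros((80, 80), np.uint8)
        mask[40:43, 5:41] = 1                       # stem
        for i in range(35):                         # two arms
            mask[40 - i:43 - i, 40 + i] = 1
            mask[40 + i:43 + i, 40 + i] = 1
        skel = octa.skeletonize_and_graph(
            octa.BinaryAngiogram(mask=mask, pixel_pitch=2.0))
        segments = octa.extract_segments(skel)
        assert len(segments) == 3

    @pytest.mark.parametrize("spec,seed", [
        (TreeSpec(n_roots=1, depth=2), 0),
        (TreeSpec(n_roots=2, depth=2), 0),
        (TreeSpec(n_roots=1, depth=3), 0),
    ])
    def test_rendered_tree_segment_count_matches_truth(self, spec, seed):
        # well-separated trees round-trip their segment count exactly
        angio, truth = gen_retina_image(spec, seed=seed)
        cleaned = octa.clean_mask(angio.mask)
        skel = octa.skeletonize_and_graph(octa.BinaryAngiogram(
            mask=cleaned.astype(np.uint8), pixel_pitch=angio.pixel_pitch))
        segments = octa.extract_segments(skel)
        assert len(segments) == len(truth)


class TestResistance:
    def test_direct_substitution(self):
        r = octa.segment_resistance(1.0, 1.0)
        assert r == pytest.approx(8.0 * 2.084e-3 / np.pi)

    def test_r4_scaling(self):
        assert octa.segment_resistance(100.0, 10.0) == pytest.approx(
            octa.segment_resistance(100.0, 5.0) / 16.0)

    def test_generator_truth_table_consistent_with_formula(self):
        _, truth = gen_retina_image(seed=3)
        expect = 8.0 * octa.BLOOD_VISCOSITY * truth["length_um"] / (
            np.pi * truth["radius_um"] ** 4)
        np.testing.assert_allclose(truth["resistance"], expect, rtol=1e-12)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            octa.segment_resistance(10.0, 0.0)

    def test_density_pitch_invariant_resistance_scales(self):
        # same geometry at two pitches: density identical, resistance of a
        # matched segment scales as pitch^-3 (l ~ pitch, r ~ pitch)
        r_coarse = octa.segment_resistance(100.0, 10.0)
        r_fine = octa.segment_resistance(200.0, 20.0)
        assert r_fine == pytest.approx(r_coarse / 8.0)


class TestDensity:
    def test_all_vessel_region_is_one(self):
        assert octa.vessel_density(np.ones((5, 5)), np.ones((5, 5))) == 1.0

    def test_half_vessel(self):
        mask = np.zeros((4, 4))
        mask[:2] = 1
        assert octa.vessel_density(mask, np.ones((4, 4))) == 0.5

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            octa.vessel_density(np.ones((4, 4)), np.zeros((4, 4)))


class TestSectors:
    def geometry(self, eye="left", pitch=10.0):
        return octa.SectorGeometry(center=(150.0, 150.0), pixel_pitch=pitch,
                                   eye=eye)

    def seg_at(self, y, x, r=10.0):
        return octa.VesselSegment(path=[(y, x)] * 3, length_um=100.0,
                                  radius_um=r)

    def test_central_only_means_quadrants_missing(self):
        geom = self.geometry()
        segments = [self.seg_at(150, 150), self.seg_at(152, 148)]
        out = octa.sector_metrics(segments, geom)
        assert out["resistance_central"] == pytest.approx(
            out["resistance_global"])
        assert np.isnan(out["resistance_superior"])

    def test_quadrant_mean(self):
        geom = self.geometry()
        # superior: 100 px above centre = 1000 µm, inside parafovea ring
        s1 = self.seg_at(50, 150, r=10.0)
        s2 = self.seg_at(60, 150, r=10.0 / 2.0 ** 0.25)  # doubles resistance
        out = octa.sector_metrics([s1, s2], geom)
        r1, r2 = s1.resistance, s2.resistance
        assert out["resistance_superior"] == pytest.approx((r1 + r2) / 2.0)

    def test_laterality_swaps_temporal_nasal(self):
        left = self.geometry("left")
        right = self.geometry("right")
        seg_east = self.seg_at(150, 250)     # image-right
        assert left.classify(seg_east.midpoint) == "temporal"
        assert right.classify(seg_east.midpoint) == "nasal"
        # mirrored image: the same vessel appears image-left
        seg_west = self.seg_at(150, 50)
        assert left.classify(seg_west.midpoint) == "nasal"
        assert right.classify(seg_west.midpoint) == "temporal"

    def test_outside_ring_unassigned(self):
        geom = self.geometry()
        out = octa.sector_metrics([self.seg_at(1, 1)], geom)
        assert out["n_segments_unassigned"] == 1
        assert np.isnan(out["resistance_global"])

    def test_assigned_counts_reconcile(self):
        angio, _ = gen_retina_image(seed=4)
        cleaned = octa.clean_mask(angio.mask)
        angio_c = octa.BinaryAngiogram(mask=cleaned.astype(np.uint8),
                                       pixel_pitch=angio.pixel_pitch)
        skel = octa.skeletonize_and_graph(angio_c)
        segments = octa.extract_segments(skel)
        geom = octa.SectorGeometry(center=angio_c.center,
                                   pixel_pitch=angio_c.pixel_pitch)
        out = octa.sector_metrics(segments, geom, angio_c)
        assigned = sum(out[f"n_segments_{s}"] for s in octa.SECTORS)
        assert assigned + out["n_segments_unassigned"] == \
            out["n_segments_total"]
        assert 0.0 <= out["density_fovea"] <= 1.0
        assert 0.0 <= out["density_parafovea"] <= 1.0


class TestGenerator:
    def test_single_vessel_truth_resistance(self):
        df = straight_vessel_df(10.0, length_um=1000.0)
        _, truth = render_segments(df, pixel_pitch=4.0, image_size=300)
        assert truth["resistance"].iloc[0] == pytest.approx(
            8.0 * 2.084e-3 * 1000.0 / (np.pi * 10.0 ** 4))

    def test_empty_tree_black_image(self):
        angio, truth = render_segments(
            pd.DataFrame(columns=["y0", "x0", "y1", "x1", "length_um",
                                  "radius_um"]),
            pixel_pitch=9.375, image_size=64)
        assert angio.mask.sum() == 0
        assert truth.empty

    def test_subpixel_radius_rejected_with_warning(self):
        df = straight_vessel_df(3.0)     # 3 µm at 9.375 µm/px < 1 px
        with pytest.warns(UserWarning, match="below one pixel"):
            angio, truth = render_segments(df, pixel_pitch=9.375,
                                           image_size=64)
        assert truth.empty
        assert angio.mask.sum() == 0

    def test_measured_resistance_within_15pct_of_truth(self):
        # rasterisation/skeleton bias on a rendered straight vessel
        df = straight_vessel_df(15.0, length_um=400.0)
        angio, truth = render_segments(df, pixel_pitch=1.0, image_size=500)
        skel = octa.skeletonize_and_graph(angio)
        segments = octa.extract_segments(skel)
        assert len(segments) == 1
        measured = segments[0].resistance
        assert measured == pytest.approx(truth["resistance"].iloc[0],
                                         rel=0.15)
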