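"""Compartment masks, radial sampling lines and front sectors."""

import numpy as np
import pytest

from traffiq.errors import TraffiqError
from traffiq.geometry import (
    CellROI,
    build_compartment_masks,
    ellipse_polygon,
    front_sector,
    load_rois_csv,
    load_rois_json,
    radial_lines,
    rasterize_polygon,
    save_rois_json,
)


def _radii(mask, center):
    yy, xx = np.nonzero(mask)
    return np.hypot(xx - center[0], yy - center[1])


class TestCompartmentMasks:
    def test_concentric_circles_give_analytic_annuli(self, circle_roi):
        # r_cell=100, r_nuc=30 → R=70; bands 0.25/0.15 → annuli 30–47.5 and 89.5–100
        masks = build_compartment_masks(circle_roi, 0.25, 0.15)
        assert masks.band_params["mean_radial_distance_px"] == pytest.approx(70, abs=0.5)
        r_peri = _radii(masks.perinuclear_mask, (105, 105))
        assert r_peri.min() >= 30 - 1 and r_peri.max() <= 47.5 + 1
        r_out = _radii(masks.peripheral_mask, (105, 105))
        assert r_out.min() >= 89.5 - 1 and r_out.max() <= 100 + 1
        assert not (masks.perinuclear_mask & masks.peripheral_mask).any()

    def test_overlapping_bands_rejected(self, circle_roi):
        with pytest.raises(TraffiqError) as e:
            build_compartment_masks(circle_roi, 0.6, 0.6)
        assert e.value.code == "bands-overlap"

    def test_nucleus_touching_membrane_keeps_masks_disjoint(self):
        # nucleus tangent to the cell boundary at (85, 45)
        roi = CellROI(
            cell_outline=ellipse_polygon((45.0, 45.0), 40.0, n_vertices=180),
            nucleus_outline=ellipse_polygon((71.0, 45.0), 14.0, n_vertices=90),
        )
        masks = build_compartment_masks(roi, 0.25, 0.15)
        assert masks.perinuclear_mask.any() and masks.peripheral_mask.any()
        assert not (masks.perinuclear_mask & masks.peripheral_mask).any()

    def test_degenerate_roi_rejected(self):
        tiny = CellROI(
            cell_outline=ellipse_polygon((5.0, 5.0), 1.5),
            nucleus_outline=ellipse_polygon((5.0, 5.0), 0.5),
        )
        with pytest.raises(TraffiqError) as e:
            build_compartment_masks(tiny)
        assert e.value.code == "degenerate-roi"

    def test_random_rois_masks_disjoint_and_contained(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r_cell = rng.uniform(12, 20)
            nf = rng.uniform(0.2, 0.5)
            roi = CellROI(
                cell_outline=ellipse_polygon(
                    (24.0, 24.0), r_cell, r_cell * rng.uniform(0.7, 1.0),
                    fourier_amplitude=0.08, rng=rng, rotation=rng.uniform(0, np.pi),
                ),
                nucleus_outline=ellipse_polygon((24.0, 24.0), nf * r_cell),
            )
            m = build_compartment_masks(roi, 0.25, 0.15)
            assert not (m.perinuclear_mask & m.peripheral_mask).any()
            assert (m.perinuclear_mask <= m.cell_mask).all()
            assert (m.peripheral_mask <= m.cell_mask).all()


class TestRadialLines:
    def test_default_even_spacing(self, circle_roi):
        segs = radial_lines(circle_roi, n_lines=3, length=50)
        assert [round(np.degrees(s.angle)) for s in segs] == [0, 120, 240]
        for s in segs:
            d = np.hypot(s.start[0] - 105, s.start[1] - 105)
            assert d == pytest.approx(100, abs=0.5)  # starts on the boundary

    def test_explicit_angle(self, circle_roi):
        (seg,) = radial_lines(circle_roi, n_lines=1, length=50, angles=[np.pi / 2])
        assert seg.start[0] == pytest.approx(105, abs=0.5)
        assert seg.start[1] == pytest.approx(205, abs=0.5)

    def test_truncation_at_centroid(self, circle_roi):
        (seg,) = radial_lines(circle_roi, n_lines=1, length=150, angles=[0.0])
        assert seg.truncated
        assert seg.length == pytest.approx(100, abs=0.5)
        assert seg.end == pytest.approx((105, 105), abs=0.5)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        cell = ellipse_polygon((60.0, 60.0), 40.0, 30.0, fourier_amplitude=0.08, rng=rng)
        nuc = ellipse_polygon((60.0, 60.0), 12.0)
        theta = 0.7

        def rot(poly):
            c, s = np.cos(theta), np.sin(theta)
            p = poly - 60.0
            return np.column_stack([c * p[:, 0] - s * p[:, 1], s * p[:, 0] + c * p[:, 1]]) + 60.0

        roi = CellROI(cell_outline=cell, nucleus_outline=nuc)
        roi_rot = CellROI(cell_outline=rot(cell), nucleus_outline=rot(nuc))
        segs = radial_lines(roi, n_lines=4, length=25)
        segs_rot = radial_lines(roi_rot, n_lines=4, length=25,
                                angles=[s.angle + theta for s in segs])
        for s, sr in zip(segs, segs_rot):
            expected = rot(np.array([s.start, s.end]))
            assert np.allclose(expected[0], sr.start, atol=0.5)
            assert np.allclose(expected[1], sr.end, atol=0.5)


class TestFrontSector:
    def test_direction_half_width(self, circle_roi):
        sec = front_sector(circle_roi, direction=0.0, half_width=np.deg2rad(60))
        assert sec.contains_points(np.array([150.0]), np.array([105.0]))[0]
        assert not sec.contains_points(np.array([60.0]), np.array([105.0]))[0]

    def test_edge_points_quarter_sector(self, circle_roi):
        sec = front_sector(circle_roi, edge_points=((205.0, 105.0), (105.0, 205.0)))
        assert sec.half_width == pytest.approx(np.pi / 4)
        assert sec.direction == pytest.approx(np.pi / 4)

    def test_coincident_edge_points_rejected(self, circle_roi):
        with pytest.raises(TraffiqError) as e:
            front_sector(circle_roi, edge_points=((205.0, 105.0), (205.0, 105.0)))
        assert e.value.code == "degenerate-sector"

    def test_sector_partition_covers_cytoplasm(self, small_circle_roi):
        masks = build_compartment_masks(small_circle_roi, 0.2, 0.1)
        nuc = rasterize_polygon(small_circle_roi.nucleus_polygon, masks.cell_mask.shape)
        cyto = masks.cell_mask & ~nuc
        k = 5
        total = 0
        for i in range(k):
            sec = front_sector(
                small_circle_roi,
                direction=(2 * i + 1) * np.pi / k,
                half_width=np.pi / k,
            )
            total += (sec.mask(cyto.shape) & cyto).sum()
        assert abs(total - cyto.sum()) <= 0.02 * masks.cell_mask.sum()


class TestRoiIO:
    def test_json_roundtrip(self, tmp_path, circle_roi):
        p = tmp_path / "rois.json"
        save_rois_json([circle_roi], p)
        (back,) = load_rois_json(p)
        assert np.allclose(back.cell_outline, circle_roi.cell_outline)
        assert np.allclose(back.nucleus_outline, circle_roi.nucleus_outline)

    def test_csv_format(self, tmp_path):
        import pandas as pd

        sq = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], dtype=float)
        nu = sq * 0.3 + 5
        rows = []
        for structure, poly in (("cell", sq), ("nucleus", nu)):
            for i, (x, y) in enumerate(poly):
                rows.append({"cell_id": "c1", "structure": structure,
                             "vertex_index": i, "x": x, "y": y})
        p = tmp_path / "rois.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        (roi,) = load_rois_csv(p)
        assert roi.cell_polygon.area == pytest.approx(400)
        assert roi.nucleus_polygon.covered_by(roi.cell_polygon)
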