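"""Focal-adhesion particle analysis, Golgi area and polarity scoring."""

import numpy as np
import pytest

from traffiq.errors import TraffiqError
from traffiq.geometry import SectorRegion, front_sector, rasterize_polygon
from traffiq.morphometrics import (
    golgi_area,
    percent_polarized,
    polarity_score,
    segment_puncta,
)
from traffiq.scene_sim import SceneConfig, simulate_scene


def _two_squares():
    img = np.zeros((32, 32))
    img[4:9, 4:9] = 100  # 25 px²
    img[20:25, 20:25] = 100
    return img


class TestSegmentPuncta:
    def test_two_squares_counted(self):
        table = segment_puncta(_two_squares(), np.ones((32, 32), bool),
                               threshold_method=50.0, min_size=4)
        assert table.count == 2
        assert table.mean_area_px2 == 25.0

    def test_min_size_filter_removes_all(self):
        table = segment_puncta(_two_squares(), np.ones((32, 32), bool),
                               threshold_method=50.0, min_size=30)
        assert table.count == 0
        assert np.isnan(table.mean_area_px2)

    def test_no_signal_is_empty_not_error(self):
        table = segment_puncta(np.zeros((16, 16)), np.ones((16, 16), bool),
                               threshold_method=1.0)
        assert table.count == 0

    def test_count_invariant_to_intensity_scaling_with_otsu(self):
        img = _two_squares() + 5.0
        mask = np.ones((32, 32), bool)
        a = segment_puncta(img, mask, threshold_method="otsu")
        b = segment_puncta(10 * img, mask, threshold_method="otsu")
        assert a.count == b.count == 2

    def test_area_conservation(self):
        rng = np.random.default_rng(2)
        img = (rng.random((64, 64)) > 0.9).astype(float) * 100
        mask = np.ones((64, 64), bool)
        table = segment_puncta(img, mask, threshold_method=50.0, min_size=2)
        if table.count:
            assert table.mean_area_px2 * table.count == pytest.approx(
                table.particles["area_px2"].sum()
            )

    def test_recovers_simulated_fa_count_and_size(self):
        cfg = SceneConfig(n_cells=3, n_fa=40, n_puncta=0, cell_radius_range=(80, 90),
                          image_size=220, seed=9)
        for scene in simulate_scene(cfg):
            mask = rasterize_polygon(scene.roi.cell_polygon, scene.images["fa"].shape)
            table = segment_puncta(scene.images["fa"], mask)
            true_mean = np.mean([f["rendered_area_px2"] for f in scene.ground_truth["fa"]])
            assert abs(table.count - 40) <= 0.05 * 40
            assert abs(table.mean_area_px2 - true_mean) <= 0.10 * true_mean


class TestGolgiArea:
    def test_uniform_blob_area(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 80
        res = golgi_area(img, np.ones((32, 32), bool), threshold_method=40.0)
        assert res["area_px2"] == 100

    def test_pixel_size_conversion(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 80
        res = golgi_area(img, np.ones((32, 32), bool), threshold_method=40.0,
                         pixel_size=0.2)
        assert res["area_um2"] == pytest.approx(4.0)

    def test_additivity_of_blobs(self):
        img = np.zeros((40, 40))
        img[2:8, 2:12] = 80  # 60 px²
        img[30:35, 30:38] = 80  # 40 px²
        res = golgi_area(img, np.ones((40, 40), bool), threshold_method=40.0)
        assert res["area_px2"] == 100


class TestPolarity:
    def test_all_intensity_inside_sector(self):
        img = np.zeros((64, 64))
        img[30:34, 50:60] = 100  # along +x from center
        sector = SectorRegion(apex=(32, 32), direction=0.0, half_width=np.deg2rad(60))
        res = polarity_score(img, sector, basis="intensity",
                             cell_mask=np.ones((64, 64), bool), threshold_method=50.0)
        assert res.in_sector_fraction == 1.0
        assert res.polarized

    def test_uniform_ring_gives_sector_fraction(self, circle_roi):
        # constant-intensity ring: a 120° sector holds 1/3 of the signal
        yy, xx = np.mgrid[0:220, 0:220]
        r = np.hypot(xx - 105, yy - 105)
        img = ((r > 60) & (r < 80)).astype(float) * 100
        sector = front_sector(circle_roi, direction=1.0, half_width=np.deg2rad(60))
        res = polarity_score(img, sector, basis="intensity",
                             cell_mask=np.ones((220, 220), bool), threshold_method=50.0)
        assert res.in_sector_fraction == pytest.approx(1 / 3, abs=0.01)
        assert not res.polarized

    def test_count_basis_three_of_four(self):
        img = np.zeros((64, 64))
        for x, y in ((50, 32), (50, 36), (45, 28), (10, 32)):  # 3 in +x sector
            img[y - 1 : y + 2, x - 1 : x + 2] = 100
        table = segment_puncta(img, np.ones((64, 64), bool), threshold_method=50.0)
        sector = SectorRegion(apex=(32, 32), direction=0.0, half_width=np.deg2rad(60))
        res = polarity_score(table, sector, basis="count")
        assert res.in_sector_fraction == 0.75
        assert res.polarized

    def test_exact_half_is_not_polarized(self):
        img = np.zeros((64, 64))
        img[30:34, 50:54] = 100
        img[30:34, 10:14] = 100
        sector = SectorRegion(apex=(32, 32), direction=0.0, half_width=np.deg2rad(80))
        res = polarity_score(img, sector, basis="intensity",
                             cell_mask=np.ones((64, 64), bool), threshold_method=50.0)
        assert res.in_sector_fraction == pytest.approx(0.5)
        assert not res.polarized

    def test_no_structures_rejected(self):
        sector = SectorRegion(apex=(8, 8), direction=0.0, half_width=1.0)
        with pytest.raises(TraffiqError) as e:
            polarity_score(np.zeros((16, 16)), sector, basis="intensity",
                           cell_mask=np.ones((16, 16), bool), threshold_method=1.0)
        assert e.value.code == "no-structures"

    def test_percent_polarized(self):
        assert percent_polarized([True, True, False, False]) == 0.5
        assert percent_polarized([True] * 4) == 1.0
        with pytest.raises(TraffiqError):
            percent_polarized([])

    def test_uniform_placement_calibrates_to_sector_fraction(self):
        """Uniformly placed FAs: mean in-sector fraction ≈ 120°/360° = 1/3."""
        cfg = SceneConfig(n_cells=25, n_fa=40, n_puncta=0, cell_radius_range=(80, 90),
                          image_size=220, fa_front_bias=None, seed=10)
        fracs = []
        for scene in simulate_scene(cfg):
            sector = front_sector(scene.roi, direction=0.0, half_width=np.deg2rad(60))
            mask = rasterize_polygon(scene.roi.cell_polygon, scene.images["fa"].shape)
            res = polarity_score(scene.images["fa"], sector, basis="intensity",
                                 cell_mask=mask)
            fracs.append(res.in_sector_fraction)
        se = np.sqrt((1 / 3) * (2 / 3) / (25 * 40))
        assert abs(np.mean(fracs) - 1 / 3) <= 3 * se + 0.01
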