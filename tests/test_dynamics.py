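"""Track statistics, maturation series and plate/densitometry kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traffiq.dynamics import (
    KineticsRecord,
    Track,
    degradation_curve,
    endocytosis_fraction,
    endocytosis_fraction_from_plate,
    maturation_series,
    recycled_fraction,
    track_stats,
    tracks_from_table,
)
from traffiq.errors import TraffiqError
from traffiq.geometry import rasterize_polygon
from traffiq.scene_sim import (
    simulate_decay,
    simulate_maturation_movie,
    simulate_plate,
    simulate_tracks,
)


class TestTrackStats:
    def test_straight_track(self):
        t = np.arange(10.0)
        tr = Track("a", t, 2 * t, np.zeros(10))
        st_ = track_stats(tr)
        assert st_.speed == pytest.approx(2.0)
        assert st_.directionality == pytest.approx(1.0)
        assert st_.net_displacement == pytest.approx(18.0)

    def test_out_and_back(self):
        tr = Track("b", [0, 1, 2], [0, 5, 0], [0, 0, 0])
        st_ = track_stats(tr)
        assert st_.net_displacement == 0.0
        assert st_.directionality == 0.0
        assert st_.path_length == 10.0

    def test_stationary_track_zero_speed(self):
        st_ = track_stats(Track("c", [0, 1, 2], [3, 3, 3], [4, 4, 4]))
        assert st_.speed == 0.0 and st_.directionality == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(TraffiqError) as e:
            track_stats(Track("d", [0], [0], [0]))
        assert e.value.code == "track-too-short"

    def test_non_monotone_time_rejected(self):
        with pytest.raises(TraffiqError) as e:
            track_stats(Track("e", [0, 2, 1], [0, 1, 2], [0, 0, 0]))
        assert e.value.code == "bad-timebase"

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=30))
    def test_directionality_bounded_by_path(self, points):
        xs, ys = zip(*points)
        tr = Track("p", np.arange(len(points), dtype=float), np.array(xs), np.array(ys))
        st_ = track_stats(tr)
        assert 0.0 <= st_.directionality <= 1.0 + 1e-12
        assert st_.path_length >= st_.net_displacement - 1e-9

    def test_brownian_directionality_decays_with_length(self):
        # directional persistence of a random walk shrinks roughly as n^(-1/2)
        means = []
        for n_frames in (10, 40, 160):
            table, _ = simulate_tracks(150, motion="brownian", sigma=0.5,
                                       n_frames=n_frames, seed=17)
            d = [track_stats(t).directionality for t in tracks_from_table(table)]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]
        assert means[0] / means[2] > 2.0  # ~sqrt(16) ideally, loose bound

    def test_directed_exceeds_brownian_persistence(self):
        directed, _ = simulate_tracks(60, motion="directed", v=0.5, jitter=0.05,
                                      n_frames=50, seed=18)
        brown, _ = simulate_tracks(60, motion="brownian", sigma=0.5,
                                   n_frames=50, seed=19)
        d1 = np.mean([track_stats(t).directionality for t in tracks_from_table(directed)])
        d0 = np.mean([track_stats(t).directionality for t in tracks_from_table(brown)])
        assert d1 > d0


class TestMaturation:
    def test_constant_movie_flat_series(self):
        movie = np.full((5, 16, 16), 50.0)
        ser = maturation_series(movie, np.ones((16, 16), bool), vesicle_threshold=10,
                                subtract_background=False)
        assert np.allclose(ser.mean_vesicle_intensity, 50.0)

    def test_linear_ramp_recovered(self):
        movie, roi, truth = simulate_maturation_movie(ramp_factor=2.0, n_frames=10, seed=3)
        mask = rasterize_polygon(roi.cell_polygon, movie[0].shape)
        ser = maturation_series(movie, mask, vesicle_threshold=40,
                                normalization="fold-over-t0")
        assert ser.mean_vesicle_intensity[-1] == pytest.approx(2.0, abs=0.1)

    def test_faster_ramp_gives_proportional_slope(self):
        # "fast-trafficking" scenes ramp 3×, control 1.5×: slope ratio ≈ (3−1)/(1.5−1)
        ends = {}
        for name, ramp in (("fast", 3.0), ("ctl", 1.5)):
            movie, roi, _ = simulate_maturation_movie(ramp_factor=ramp, n_frames=10, seed=6)
            mask = rasterize_polygon(roi.cell_polygon, movie[0].shape)
            ser = maturation_series(movie, mask, vesicle_threshold=40,
                                    normalization="fold-over-t0")
            ends[name] = ser.mean_vesicle_intensity[-1] - 1.0
        assert ends["fast"] / ends["ctl"] == pytest.approx((3 - 1) / (1.5 - 1), rel=0.15)

    def test_empty_frame_flagged_missing(self):
        movie = np.zeros((3, 8, 8))
        movie[0, 2, 2] = movie[2, 2, 2] = 100.0
        ser = maturation_series(movie, np.ones((8, 8), bool), vesicle_threshold=50,
                                fixed_mask=False, subtract_background=False)
        assert ser.missing_frames == [1]
        assert np.isnan(ser.mean_vesicle_intensity[1])


class TestPlateKinetics:
    def test_simple_percent(self):
        rec = KineticsRecord("c", internalized=50, surface_bound_total=100)
        assert endocytosis_fraction(rec) == pytest.approx(50.0)

    def test_protein_normalization_invariance(self):
        a = KineticsRecord("c", internalized=50, surface_bound_total=100,
                           protein_norm=1.0, protein_norm_reference=1.0)
        b = KineticsRecord("c", internalized=100, surface_bound_total=200,
                           protein_norm=2.0, protein_norm_reference=2.0)
        assert endocytosis_fraction(a) == pytest.approx(endocytosis_fraction(b))

    def test_common_scaling_invariance(self):
        plate, _ = simulate_plate(0.3, 0.6, noise_cv=0.05, seed=4)
        a = endocytosis_fraction_from_plate(plate)
        plate2 = plate.copy()
        plate2["signal"] *= 7.0
        b = endocytosis_fraction_from_plate(plate2)
        assert np.allclose(a["percent_internalized"], b["percent_internalized"])

    def test_zero_reference_rejected(self):
        rec = KineticsRecord("c", internalized=50, surface_bound_total=0)
        with pytest.raises(TraffiqError) as e:
            endocytosis_fraction(rec)
        assert e.value.code == "zero-reference"

    def test_noise_free_plate_exact(self):
        plate, _ = simulate_plate(0.3, 0.6, noise_cv=0.0, seed=0)
        res = endocytosis_fraction_from_plate(plate)
        assert res["percent_internalized"].iloc[0] == pytest.approx(30.0)

    def test_noisy_plate_recovery(self):
        plate, _ = simulate_plate(0.3, 0.6, n_replicates=6, noise_cv=0.05, seed=1)
        res = endocytosis_fraction_from_plate(plate)
        assert abs(res["percent_internalized"].iloc[0] - 30.0) <= 3.0


class TestRecycling:
    def test_fraction(self):
        rec = KineticsRecord("c", internalized=100, surface_bound_total=100,
                             remaining_after_strip=40)
        frac, clamped = recycled_fraction(rec)
        assert frac == pytest.approx(0.6) and not clamped

    def test_nothing_recycled(self):
        rec = KineticsRecord("c", internalized=100, surface_bound_total=100,
                             remaining_after_strip=100)
        assert recycled_fraction(rec) == (0.0, False)

    def test_noise_overshoot_clamped_and_flagged(self):
        rec = KineticsRecord("c", internalized=100, surface_bound_total=100,
                             remaining_after_strip=105)
        frac, clamped = recycled_fraction(rec)
        assert frac == 0.0 and clamped

    def test_zero_internalized_rejected(self):
        with pytest.raises(TraffiqError) as e:
            recycled_fraction(KineticsRecord("c", 0, 100))
        assert e.value.code == "zero-internalized"


class TestDegradation:
    def test_flat_control_normalization(self):
        curve = degradation_curve([100, 50, 25], [10, 10, 10], [0, 30, 60], fit=False)
        assert np.allclose(curve.normalized_intensity, [100, 50, 25])

    def test_control_shift_cancels(self):
        curve = degradation_curve([100, 200], [10, 20], [0, 30], fit=False)
        assert np.allclose(curve.normalized_intensity, [100, 100])

    def test_zero_control_rejected(self):
        with pytest.raises(TraffiqError) as e:
            degradation_curve([100, 50], [10, 0], [0, 30])
        assert e.value.code == "zero-loading-control"

    def test_half_life_fit_on_simulated_decay(self):
        dens, truth = simulate_decay(30.0, np.arange(0, 121, 15), noise_cv=0.05, seed=5)
        curve = degradation_curve(dens["band"].to_numpy(), dens["control"].to_numpy(),
                                  dens["time_min"].to_numpy())
        assert curve.fitted_half_life == pytest.approx(30.0, rel=0.10)
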