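import numpy as np
import pandas as pd
import pytest

from condenscan import dissolution as dz
from condenscan import simkit


def _det(frame, x, y, quality=100.0, intensity=1000.0):
    return {"frame": frame, "x_px": float(x), "y_px": float(y),
            "quality": quality, "radius_um": 0.3,
            "total_intensity": intensity}


class TestDetectFociLog:
    def test_single_blob_detected_at_center(self):
        img = np.full((60, 60), 100.0)
        simkit.add_gaussian_spot(img, 30.0, 25.0, 3.2, 50000.0)
        det = dz.detect_foci_log(img, pixel_size=0.066, quality_threshold=30.0)
        assert len(det) == 1
        assert det.x_px[0] == pytest.approx(30.0, abs=1.0)
        assert det.y_px[0] == pytest.approx(25.0, abs=1.0)

    def test_blob_below_threshold_not_reported(self):
        img = np.full((60, 60), 100.0)
        simkit.add_gaussian_spot(img, 30.0, 25.0, 3.2, 500.0)
        strong = dz.detect_foci_log(img, 0.066, quality_threshold=1.0)
        q = strong.quality.max()
        det = dz.detect_foci_log(img, 0.066, quality_threshold=2 * q)
        assert len(det) == 0

    def test_two_separated_blobs(self):
        img = np.full((60, 90), 100.0)
        simkit.add_gaussian_spot(img, 20.0, 30.0, 3.2, 50000.0)
        simkit.add_gaussian_spot(img, 65.0, 30.0, 3.2, 50000.0)
        det = dz.detect_foci_log(img, 0.066, quality_threshold=30.0)
        assert len(det) == 2


class TestLinkFoci:
    def test_two_frame_gap_bridged_within_distance(self):
        rows = [_det(0, 10, 10), _det(1, 10.5, 10), _det(4, 11.5, 10),
                _det(5, 12, 10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        assert linked.track_id.nunique() == 1   # gap of 2 frames, 1 px apart

    def test_three_frame_gap_splits_track(self):
        rows = [_det(0, 10, 10), _det(1, 10.5, 10), _det(5, 11, 10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        assert linked.track_id.nunique() == 2   # gap of 3 > max_gap 2

    def test_jump_beyond_linking_distance_not_linked(self):
        rows = [_det(0, 10, 10), _det(1, 16, 10)]   # 6 px > 3 px gate
        linked = dz.link_foci(pd.DataFrame(rows))
        assert linked.track_id.nunique() == 2

    def test_gap_close_distance_respected(self):
        rows = [_det(0, 10, 10), _det(3, 18, 10)]   # gap 2, but 8 px away
        linked = dz.link_foci(pd.DataFrame(rows))
        assert linked.track_id.nunique() == 2

    def test_programmed_dropout_streams_match_oracle(self, rng):
        """Track count equals the combinatorial expectation for streams
        of well-separated foci with programmed dropouts."""
        for _ in range(30):
            n_foci = rng.integers(1, 4)
            n_frames = 12
            rows, expected_tracks = [], 0
            for k in range(n_foci):
                x = 15.0 + 25.0 * k
                # drop a random set of frames; each run of >2 missing
                # frames starts a new track
                present = rng.random(n_frames) > 0.25
                present[0] = True
                gaps = 0
                prev = None
                for f in range(n_frames):
                    if present[f]:
                        rows.append(_det(f, x + 0.2 * f, 20.0))
                        if prev is None or f - prev - 1 > 2:
                            expected_tracks += 1
                        prev = f
            linked = dz.link_foci(pd.DataFrame(rows))
            assert linked.track_id.nunique() == expected_tracks


class TestFilterFocusTracks:
    def test_track_starting_late_removed(self):
        rows = [_det(0, 10, 10), _det(1, 10, 10),
                _det(3, 40, 10), _det(4, 40, 10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        kept, removed = dz.filter_focus_tracks(
            linked, 5, dz.DissolutionContext(cells_divided_or_grew=True))
        assert kept.track_id.nunique() == 1
        assert any("first frame" in r for r in removed.values())

    def test_no_growth_movie_removes_all_tracks(self):
        rows = [_det(0, 10, 10), _det(1, 10, 10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        kept, removed = dz.filter_focus_tracks(
            linked, 2, dz.DissolutionContext(cells_divided_or_grew=False))
        assert len(kept) == 0
        assert all("grow" in r or "divide" in r for r in removed.values())

    def test_first_frame_exclusion_list(self):
        rows = [_det(0, 10, 10), _det(1, 10, 10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        kept, removed = dz.filter_focus_tracks(
            linked, 2, dz.DissolutionContext(
                first_frame_exclusions=[(10.0, 10.0)],
                cells_divided_or_grew=True))
        assert len(kept) == 0

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["frame", "x_px", "y_px", "quality",
                                      "total_intensity", "track_id"])
        kept, removed = dz.filter_focus_tracks(
            empty, 5, dz.DissolutionContext(cells_divided_or_grew=True))
        assert len(kept) == 0 and removed == {}


class TestLifespanStats:
    def test_counting_at_15min_intervals(self):
        rows = [_det(f, 10, 10) for f in range(10)]
        linked = dz.link_foci(pd.DataFrame(rows))
        table, summary = dz.lifespan_stats(linked, n_frames=40,
                                           frame_interval=900.0)
        assert table.lifespan_h[0] == pytest.approx(2.5)
        assert not table.censored[0]

    def test_track_reaching_movie_end_censored(self):
        rows = [_det(f, 10, 10) for f in range(5)]
        linked = dz.link_foci(pd.DataFrame(rows))
        table, summary = dz.lifespan_stats(linked, n_frames=5,
                                           frame_interval=900.0)
        assert table.censored[0]
        assert summary["n_censored"] == 1

    def test_aggregate_movie_full_duration_censored(self):
        mov = simkit.simulate_dissolution_series("aggregate", n_frames=40,
                                                 rng=9)
        _, table, summary = dz.analyze_dissolution_movie(
            mov.stack, context=dz.DissolutionContext(cells_divided_or_grew=True))
        assert summary["n_tracks"] == 1
        assert summary["n_censored"] == 1
        assert summary["mean_lifespan_h"] == pytest.approx(10.0)

    def test_programmed_dissolution_within_one_frame(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            mov = simkit.simulate_dissolution_series(
                "condensate", initial_concentration_uM=rng.uniform(55, 110),
                n_frames=40, rng=int(rng.integers(1 << 31)),
                division_rule={"type": "deterministic",
                               "molecule_fraction": 0.5})
            kept, table, _ = dz.analyze_dissolution_movie(
                mov.stack,
                context=dz.DissolutionContext(cells_divided_or_grew=True))
            measured = table.lifespan_h.max() * 3600 / mov.frame_interval
            assert abs(measured - mov.lifespan_frames) <= 1


class TestIntensityCourse:
    def test_first_frame_normalized_to_one(self):
        rows = [_det(f, 10, 10, intensity=500.0 - 20 * f) for f in range(5)]
        linked = dz.link_foci(pd.DataFrame(rows))
        per, pop = dz.focus_intensity_course(linked)
        first = per.sort_values("frame").normalized_intensity.iloc[0]
        assert first == 1.0

    def test_aggregate_course_flat_condensate_decreasing(self):
        flat_mov = simkit.simulate_dissolution_series("aggregate",
                                                      n_frames=30, rng=21)
        dis_mov = simkit.simulate_dissolution_series(
            "condensate", initial_concentration_uM=100.0, n_frames=30, rng=22,
            division_rule={"type": "deterministic", "molecule_fraction": 0.5})
        out = {}
        for name, mov in (("agg", flat_mov), ("cond", dis_mov)):
            kept, _, _ = dz.analyze_dissolution_movie(
                mov.stack,
                context=dz.DissolutionContext(cells_divided_or_grew=True))
            per, pop = dz.focus_intensity_course(kept, mov.frame_interval)
            out[name] = pop
        agg = out["agg"]["mean"]
        assert agg.iloc[-5:].mean() == pytest.approx(1.0, abs=0.15)
        cond = out["cond"]["mean"]
        # monotone decreasing trend until dissolution
        assert cond.iloc[-1] < 0.5
        diffs = np.diff(cond.to_numpy())
        assert (diffs < 0.05).all()
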