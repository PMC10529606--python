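import numpy as np
import pandas as pd
import pytest

from puptrack.qc import great_circle_distance
from puptrack.trips import (ColonyGeometry, build_trip_table, classify_haulout,
                            classify_trip_type, derive_animal_covariates,
                            segment_trips, trip_metrics)

from conftest import make_fixes

OFFSHORE = (-58.3, 43.2)  # over a deep basin, far from the colony


class TestHauloutClassification:
    def test_tag_flag_takes_precedence(self, bathy, colony):
        fx = make_fixes([0], [OFFSHORE[0]], [OFFSHORE[1]], tag_haulout=True)
        calls = classify_haulout(fx, bathy, colony)
        assert calls["is_haulout"].iloc[0]
        assert calls["haulout_reason"].iloc[0] == "tag_flag"

    def test_depth_boundary_inclusive(self, colony):
        # a synthetic one-cell grid pinned at exactly 5 m depth
        from puptrack.bathymetry import BathymetryGrid
        grid = BathymetryGrid(np.array([-58.4, -58.3, -58.2]),
                              np.array([43.1, 43.2, 43.3]),
                              np.full((3, 3), -5.0), 0.1)
        fx = make_fixes([0], [-58.3], [43.2])
        calls = classify_haulout(fx, grid, colony)
        assert calls["is_haulout"].iloc[0]
        assert calls["haulout_reason"].iloc[0] == "shallow_depth"

    def test_colony_radius_rule(self, bathy, colony):
        # ~9.9 km north of the island axis, water deeper than 5 m
        lat = 43.93 + 9.9 / 111.2
        fx = make_fixes([0], [-59.91], [lat])
        calls = classify_haulout(fx, None, colony)
        assert calls["haulout_reason"].iloc[0] == "colony_radius"
        far = make_fixes([0], [-59.91], [43.93 + 10.5 / 111.2])
        assert not classify_haulout(far, None, colony)["is_haulout"].iloc[0]

    def test_polyline_beats_centre_point_at_island_ends(self, colony):
        # near the island's western tip: within 10 km of the axis but ~21 km
        # from the centre point
        tip_lon = -59.91 - 21.0 / (111.2 * np.cos(np.radians(43.93)))
        fx = make_fixes([0], [tip_lon], [43.99])
        calls = classify_haulout(fx, None, colony)
        assert calls["is_haulout"].iloc[0]
        assert great_circle_distance((tip_lon, 43.99), (-59.91, 43.93)) > 10.0


def _calls(times_h, haulout_pattern, lon=OFFSHORE[0], lat=OFFSHORE[1]):
    n = len(times_h)
    fx = make_fixes(times_h, np.full(n, lon) + 0.001 * np.arange(n),
                    np.full(n, lat))
    fx["is_haulout"] = list(haulout_pattern)
    fx["haulout_reason"] = ["tag_flag" if h else "none" for h in haulout_pattern]
    return fx


class TestSegmentation:
    def test_bounded_long_bout_is_one_complete_trip(self):
        calls = _calls([0, 1, 15, 31, 32], [True, False, False, False, True])
        trips, excluded = segment_trips(calls)
        assert len(trips) == 1 and not excluded
        assert trips[0].complete
        assert trips[0].duration_days == pytest.approx(30 / 24)

    def test_short_bout_excluded(self):
        calls = _calls([0, 1, 10, 21, 22], [True, False, False, False, True])
        trips, excluded = segment_trips(calls)
        assert not trips and len(excluded) == 1

    def test_stream_end_gives_incomplete_trip(self):
        calls = _calls([0, 1, 20, 41], [True, False, False, False])
        trips, _ = segment_trips(calls)
        assert len(trips) == 1
        assert not trips[0].complete
        assert trips[0].destination is None

    def test_partition_property_on_simulated_stream(self, bathy, colony,
                                                    small_study):
        from puptrack.qc import filter_fixes
        fx = small_study["fixes"]
        pid = fx["id"].iloc[0]
        kept, _ = filter_fixes(fx[fx["id"] == pid].reset_index(drop=True))
        calls = classify_haulout(kept, bathy, colony)
        trips, excluded = segment_trips(calls)
        n_at_sea = int((~calls["is_haulout"]).sum())
        n_assigned = sum(len(t.fixes) for t in trips) + sum(len(b) for b in excluded)
        assert n_assigned == n_at_sea
        # chronology: trips disjoint and ordered
        for a, b in zip(trips, trips[1:]):
            assert a.end < b.start

    def test_trips_match_simulated_haulout_schedule(self, bathy, colony,
                                                    small_study):
        from puptrack.qc import filter_fixes
        ok = total = 0
        for path, truth in zip(small_study["paths"], small_study["truths"]):
            pid = truth.id
            fx = small_study["fixes"]
            kept, _ = filter_fixes(fx[fx["id"] == pid].reset_index(drop=True))
            calls = classify_haulout(kept, bathy, colony)
            trips, _ = segment_trips(calls)
            tol = pd.Timedelta(hours=9)  # one latent step + fix spacing
            for start, end in truth.haulout_schedule:
                total += 1
                if any(abs(t.end - start) <= tol or abs(t.start - end) <= tol
                       for t in trips):
                    ok += 1
        assert total > 0
        assert ok / total > 0.7  # colony/shallow zones extend haulouts slightly


class TestTripMetrics:
    def test_two_fix_arithmetic(self):
        from puptrack.trips import Trip
        lat = 44.0
        lon0 = OFFSHORE[0]
        # 48 km due east at this latitude, 24 h apart
        dlon = float(np.degrees(48.0 / (6371.0 * np.cos(np.radians(lat)))))
        fx = _calls([0, 24], [False, False])
        fx["lat"] = lat
        fx.loc[1, "lon"] = lon0 + dlon
        fx.loc[0, "lon"] = lon0
        trip = Trip("X1-T01", "X1", 1, fx["time"].iloc[0], fx["time"].iloc[1],
                    fx, None, None, True)
        m = trip_metrics(trip)
        assert m["duration_d"] == pytest.approx(1.0)
        assert m["distance_km"] == pytest.approx(48.0, rel=0.01)
        assert m["speed_kmh"] == pytest.approx(2.0, rel=0.01)

    def test_zigzag_distance_equals_haversine_oracle(self):
        lons = [-58.3, -58.1, -58.35, -58.0, -58.2]
        lats = [43.2, 43.35, 43.4, 43.5, 43.6]
        calls = _calls([0, 10, 20, 30, 40], [False] * 5)
        calls["lon"] = lons
        calls["lat"] = lats
        trips, _ = segment_trips(calls)
        m = trip_metrics(trips[0])
        oracle = sum(
            great_circle_distance((lons[i], lats[i]), (lons[i + 1], lats[i + 1]))
            for i in range(4))
        assert m["distance_km"] == pytest.approx(float(oracle), rel=1e-12)

    def test_haulout_duration_fix_to_fix(self):
        calls = _calls([0, 30, 31, 64.6, 90],
                       [False, False, True, False, False])
        trips, _ = segment_trips(calls)
        assert len(trips) == 2
        m = trip_metrics(trips[0], trips[1], calls)
        assert m["haulout_duration_h"] == pytest.approx(33.6)


class TestTripTypes:
    def _trip(self, origin, destination):
        calls = _calls([0, 15, 30], [False] * 3)
        trips, _ = segment_trips(calls)
        t = trips[0]
        t.origin, t.destination, t.complete = origin, destination, True
        return t

    def test_types(self, colony):
        col = (-59.91, 43.93)
        bank = (-58.72, 44.58)
        other = (-62.05, 42.95)
        assert classify_trip_type(self._trip(col, col), colony) == "A"
        assert classify_trip_type(self._trip(col, bank), colony) == "B"
        assert classify_trip_type(self._trip(bank, other), colony) == "C"

    def test_incomplete(self, colony):
        t = self._trip((-59.91, 43.93), None)
        t.complete = False
        assert classify_trip_type(t, colony) == "incomplete"


class TestAnimalCovariates:
    def test_week_boundary(self):
        calls = _calls([0, 30, 6.9 * 24, 7.1 * 24, 7.1 * 24 + 30],
                       [False, False, True, False, False])
        trips, _ = segment_trips(calls)
        pup = {"wean_date": pd.Timestamp("2016-01-11")}
        cov = derive_animal_covariates(pup, trips, deployment_days=69)
        assert cov["weeks"][trips[0].id] == 1
        assert cov["weeks"][trips[1].id] == 2

    def test_postwean_and_frequency(self):
        calls = _calls([0, 30, 31, 62, 100, 101, 140, 170],
                       [False, False, True, False, False, True, False, False])
        trips, _ = segment_trips(calls)
        pup = {"wean_date": pd.Timestamp("2016-01-11")}
        cov = derive_animal_covariates(pup, trips, deployment_days=69)
        assert cov["postwean_days"] == pytest.approx(21.0)
        complete = [t for t in trips if t.complete]
        assert cov["trip_frequency"] == pytest.approx(len(complete) / 69)

    def test_four_trips_over_69_days(self):
        # the deployment-table arithmetic: 4 complete trips / 69 d = 0.058
        times, mask = [], []
        t = 0.0
        for _ in range(4):
            times += [t, t + 15, t + 30]
            mask += [False, False, False]
            times += [t + 31]
            mask += [True]
            t += 40
        calls = _calls(times, mask)
        trips, _ = segment_trips(calls)
        cov = derive_animal_covariates({}, trips, deployment_days=69)
        assert cov["trip_frequency"] == pytest.approx(4 / 69, abs=1e-12)


def test_trip_table_types_and_weeks(bathy, colony, small_study):
    from puptrack.qc import filter_fixes
    kept, _ = filter_fixes(small_study["fixes"])
    calls = classify_haulout(kept, bathy, colony)
    table = build_trip_table(calls, colony)
    assert set(table.loc[table["complete"], "trip_type"]) <= {"A", "B", "C"}
    assert (table.loc[~table["complete"], "trip_type"] == "incomplete").all()
    assert (table["week_at_end"] >= 1).all()
    assert (table["duration_d"] > 1.0).all()
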