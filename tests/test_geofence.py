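"""Geofence dwell-time detection: distances, range tests, the hysteresis
state machine, and daily-hour accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from dwellsurv import (
    ConfigurationError,
    GeofenceParams,
    GeoPoint,
    GpsFix,
    InputError,
    Workplace,
    WorkSession,
    daily_records,
    daily_work_hours,
    detect_sessions,
    fix_in_range,
    haversine_km,
    overtime,
)
from dwellsurv.geofence import EARTH_RADIUS_KM

from conftest import TZ, make_trace, ts

WORK = GeoPoint(25.04, 121.52)
FAR = GeoPoint(25.04, 121.70)  # ~18 km east, well outside the fence


def spherical_law_of_cosines_km(a: GeoPoint, b: GeoPoint) -> float:
    """Independent great-circle oracle."""
    p1, p2 = math.radians(a.lat), math.radians(b.lat)
    dl = math.radians(b.lon - a.lon)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_identity(self):
        assert haversine_km(GeoPoint(0, 0), GeoPoint(0, 0)) == 0.0

    def test_equator_degree_arc(self):
        # one degree of longitude on the equator is R * pi/180
        expected = EARTH_RADIUS_KM * math.pi / 180.0
        assert haversine_km(GeoPoint(0, 0), GeoPoint(0, 1)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_against_law_of_cosines_oracle(self):
        rng = np.random.default_rng(42)
        lat = rng.uniform(-89, 89, 10_000)
        lon = rng.uniform(-180, 180, 10_000)
        lat2 = rng.uniform(-89, 89, 10_000)
        lon2 = rng.uniform(-180, 180, 10_000)
        for i in range(10_000):
            a, b = GeoPoint(lat[i], lon[i]), GeoPoint(lat2[i], lon2[i])
            d = haversine_km(a, b)
            assert d == haversine_km(b, a)
            assert d >= 0
            assert d == pytest.approx(
                spherical_law_of_cosines_km(a, b), rel=1e-9, abs=1e-9
            )

    def test_longitude_wrap_normalization(self):
        assert GeoPoint(0, 181.0).lon == pytest.approx(-179.0)
        assert haversine_km(GeoPoint(0, 181.0), GeoPoint(0, -179.0)) == 0.0

    def test_bad_latitude_rejected(self):
        with pytest.raises(InputError):
            GeoPoint(91.0, 0.0)


def point_at_km_east(origin: GeoPoint, km: float) -> GeoPoint:
    """Exact arc of `km` along the equator-parallel great circle at lat 0."""
    return GeoPoint(origin.lat, origin.lon + math.degrees(km / EARTH_RADIUS_KM))


class TestFixInRange:
    @pytest.mark.parametrize("km,expected", [(0.5, True), (1.5, False)])
    def test_distance_decision(self, km, expected):
        wp = Workplace("w0", GeoPoint(0.0, 0.0))
        fix = GpsFix("u0", ts("2018-09-03", "09:00"), point_at_km_east(wp.point, km))
        inr, wid = fix_in_range(fix, [wp], GeofenceParams())
        assert inr is expected
        assert wid == "w0"

    def test_boundary_distance_is_in_range(self):
        """Closed-ball decision: a fix at distance exactly equal to the
        radius counts as in range."""
        wp = Workplace("w0", GeoPoint(0.0, 0.0))
        fix = GpsFix("u0", ts("2018-09-03", "09:00"),
                     point_at_km_east(wp.point, 1.0))
        exact = haversine_km(fix.point, wp.point)
        inr, _ = fix_in_range(fix, [wp], GeofenceParams(radius_km=exact))
        assert inr
        assert fix_in_range(
            fix, [wp], GeofenceParams(radius_km=exact * (1 - 1e-12))
        )[0] is False

    def test_nearest_workplace_and_tie_order(self):
        w1 = Workplace("first", GeoPoint(0, 0.5))
        w2 = Workplace("second", GeoPoint(0, -0.5))
        fix = GpsFix("u0", ts("2018-09-03", "09:00"), GeoPoint(0, 0))
        _, wid = fix_in_range(fix, [w1, w2])
        assert wid == "first"  # equidistant: registration order wins

    def test_no_workplaces_is_config_error(self):
        fix = GpsFix("u0", ts("2018-09-03", "09:00"), GeoPoint(0, 0))
        with pytest.raises(ConfigurationError):
            fix_in_range(fix, [])

    def test_more_than_five_workplaces_rejected(self):
        fix = GpsFix("u0", ts("2018-09-03", "09:00"), GeoPoint(0, 0))
        wps = [Workplace(f"w{i}", GeoPoint(0, i * 0.1)) for i in range(6)]
        with pytest.raises(ConfigurationError):
            fix_in_range(fix, wps)


class TestDetectSessions:
    def wp(self):
        return [Workplace("w0", WORK)]

    def test_commuter_day_recovers_printed_endpoints(self):
        # out of range until 08:40, in range 08:50-18:20, out afterwards
        trace = make_trace(
            "2018-09-03",
            [
                ("07:00", "08:40", False),
                ("08:50", "18:20", True),
                ("18:30", "20:00", False),
            ],
            WORK,
            FAR,
        )
        sessions = detect_sessions(trace, self.wp())
        assert len(sessions) == 1
        s = sessions[0]
        assert s.start == ts("2018-09-03", "08:50")
        assert s.end == ts("2018-09-03", "18:20")
        assert s.duration_min == pytest.approx(570.0)
        assert not s.open_at_end

    def test_run_shorter_than_confirmation_yields_nothing(self):
        trace = make_trace(
            "2018-09-03",
            [("09:00", "09:20", True), ("09:30", "11:00", False)],
            WORK,
            FAR,
        )
        assert detect_sessions(trace, self.wp()) == []

    def test_short_excursion_does_not_split(self):
        trace = make_trace(
            "2018-09-03",
            [
                ("08:00", "12:00", True),
                ("12:10", "12:20", False),
                ("12:30", "17:00", True),
                ("17:10", "18:00", False),
            ],
            WORK,
            FAR,
        )
        sessions = detect_sessions(trace, self.wp())
        assert len(sessions) == 1
        assert sessions[0].start == ts("2018-09-03", "08:00")
        assert sessions[0].end == ts("2018-09-03", "17:00")

    def test_long_excursion_splits(self):
        trace = make_trace(
            "2018-09-03",
            [
                ("08:00", "12:00", True),
                ("12:10", "12:40", False),  # out-run spans 30 min
                ("12:50", "17:00", True),
                ("17:10", "18:00", False),
            ],
            WORK,
            FAR,
        )
        sessions = detect_sessions(trace, self.wp())
        assert [(s.start, s.end) for s in sessions] == [
            (ts("2018-09-03", "08:00"), ts("2018-09-03", "12:00")),
            (ts("2018-09-03", "12:50"), ts("2018-09-03", "17:00")),
        ]

    def test_trace_hole_closes_session(self):
        trace = make_trace(
            "2018-09-03",
            [("08:00", "12:00", True), ("13:30", "17:00", True),
             ("17:10", "18:00", False)],
            WORK,
            FAR,
        )
        sessions = detect_sessions(trace, self.wp())
        assert [(s.start, s.end) for s in sessions] == [
            (ts("2018-09-03", "08:00"), ts("2018-09-03", "12:00")),
            (ts("2018-09-03", "13:30"), ts("2018-09-03", "17:00")),
        ]

    def test_open_at_trace_end_is_flagged(self):
        trace = make_trace("2018-09-03", [("08:00", "12:00", True)], WORK, FAR)
        sessions = detect_sessions(trace, self.wp())
        assert len(sessions) == 1
        assert sessions[0].open_at_end
        assert sessions[0].end == ts("2018-09-03", "12:00")

    def test_empty_trace(self):
        assert detect_sessions([], self.wp()) == []

    def test_unsorted_trace_rejected(self):
        trace = make_trace("2018-09-03", [("08:00", "10:00", True)], WORK, FAR)
        with pytest.raises(InputError):
            detect_sessions(list(reversed(trace)), self.wp())

    def test_sessions_disjoint_and_ordered_on_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = ts("2018-09-03", "06:00")
            trace = []
            inr = False
            for _k in range(rng.integers(20, 120)):
                if rng.random() < 0.15:
                    inr = not inr
                t = t + pd.Timedelta(minutes=int(rng.choice([10, 10, 10, 20, 50])))
                trace.append(GpsFix("u0", t, WORK if inr else FAR))
            sessions = detect_sessions(trace, self.wp())
            for s in sessions:
                assert s.start < s.end
            for a, b in zip(sessions, sessions[1:]):
                assert a.end < b.start

    def test_invariant_under_run_preserving_subsampling(self):
        """Finer sampling of the same presence pattern gives identical
        sessions (boundaries lie on the shared 10-min grid)."""
        segments = [
            ("07:00", "08:40", False),
            ("08:50", "18:20", True),
            ("18:30", "20:00", False),
        ]
        coarse = make_trace("2018-09-03", segments, WORK, FAR)
        fine = []
        for start, end, inr in segments:
            t, stop = ts("2018-09-03", start), ts("2018-09-03", end)
            while t <= stop:
                fine.append(GpsFix("u0", t, WORK if inr else FAR))
                t = t + pd.Timedelta(minutes=5)
        for trace in (coarse, fine):
            (s,) = detect_sessions(trace, self.wp())
            assert (s.start, s.end) == (
                ts("2018-09-03", "08:50"),
                ts("2018-09-03", "18:20"),
            )


class TestDailyHours:
    def test_single_session_hours(self):
        s = WorkSession("u0", ts("2018-09-03", "08:50"), ts("2018-09-03", "18:20"))
        assert daily_work_hours([s], s.start.date()) == pytest.approx(9.5)

    def test_no_sessions(self):
        assert daily_work_hours([], pd.Timestamp("2018-09-03").date()) == 0.0

    def test_midnight_split(self):
        s = WorkSession("u0", ts("2018-09-03", "22:00"), ts("2018-09-04", "02:00"))
        assert daily_work_hours([s], ts("2018-09-03", "00:00").date()) == pytest.approx(2.0)
        assert daily_work_hours([s], ts("2018-09-04", "00:00").date()) == pytest.approx(2.0)

    def test_daily_records_overtime_signed(self):
        s = WorkSession("u0", ts("2018-09-03", "09:00"), ts("2018-09-03", "15:00"))
        (rec,) = daily_records([s], scheduled_hours=8.0)
        assert rec.total_hours == pytest.approx(6.0)
        assert rec.overtime_hours == pytest.approx(-2.0)


class TestOvertime:
    @pytest.mark.parametrize(
        "total,sched,expected", [(10, 8, 2), (8, 8, 0), (6, 8, -2)]
    )
    def test_signed_difference(self, total, sched, expected):
        assert overtime(total, sched) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            overtime(-1, 8)
        with pytest.raises(InputError):
            overtime(8, -1)
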