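"""Haulout classification, trip segmentation, and trip metrics.

A fix is classified as hauled out when any of three conditions holds, in
this order of precedence: (i) the tag's wet/dry logic flagged a haulout,
(ii) the water column at the fix is <= 5 m deep, (iii) the fix lies within
10 km of the colony (measured to the nearest point of the island axis
polyline, because the island is 43 km long).  Maximal runs of consecutive
at-sea fixes bounded by haulout fixes (or the ends of the stream) become
candidate bouts; a bout whose at-sea span exceeds 24 h is a trip.  A trip
truncated by the end of the stream is incomplete and excluded from trip
characteristic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from puptrack.bathymetry import BathymetryGrid
from puptrack.qc import great_circle_distance

HOUR_NS = 3_600 * 10**9


@dataclass
class ColonyGeometry:
    """The colony as a polyline along the island axis, plus the haulout radius."""

    polyline: list = field(default_factory=lambda: _sable_axis())
    haulout_radius_km: float = 10.0

    def __post_init__(self) -> None:
        if not self.polyline:
            raise ValueError("colony polyline must be non-empty")
        if self.haulout_radius_km <= 0:
            raise ValueError("haulout radius must be > 0")
        self._lon = np.array([p[0] for p in self.polyline])
        self._lat = np.array([p[1] for p in self.polyline])

    def distance_km(self, lon, lat):
        """Great-circle distance (km) to the nearest polyline vertex.

        The axis polyline is densified at construction so vertex distance
        approximates distance-to-segment well below the haulout radius.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.empty(lon.shape)
        for i in range(lon.size):
            out[i] = np.min(great_circle_distance(
                (lon[i], lat[i]), (self._lon, self._lat)))
        return out if out.size > 1 else float(out[0])


def _sable_axis(center_lon: float = -59.91, center_lat: float = 43.93,
                length_km: float = 43.0, n: int = 87) -> list:
    """East-west island axis through the colony centre, densified to ~0.5 km."""
    half_deg = np.degrees(length_km / 2 / (6371.0 * np.cos(np.radians(center_lat))))
    lons = np.linspace(center_lon - half_deg, center_lon + half_deg, n)
    return [(float(lo), center_lat) for lo in lons]


def classify_haulout(fixes: pd.DataFrame, bathy: BathymetryGrid | None,
                     colony: ColonyGeometry, depth_threshold_m: float = 5.0
                     ) -> pd.DataFrame:
    """Vectorized haulout call for a fix table.

    Returns a copy with boolean ``is_haulout`` and ``haulout_reason`` in
    {tag_flag, shallow_depth, colony_radius, none}; when several conditions
    hold the first in that order is recorded.  Fixes outside the bathymetry
    grid skip the depth rule.
    """
    out = fixes.copy()
    n = len(out)
    reason = np.full(n, "none", dtype=object)

    tag = out["tag_haulout"].to_numpy(bool) if "tag_haulout" in out else np.zeros(n, bool)
    lon = out["lon"].to_numpy(float)
    lat = out["lat"].to_numpy(float)

    shallow = np.zeros(n, bool)
    if bathy is not None:
        inside = bathy.contains(lon, lat)
        depth = np.where(inside, bathy.depth_at(lon, lat), np.inf)
        shallow = depth <= depth_threshold_m

    near_colony = np.asarray(colony.distance_km(lon, lat)) <= colony.haulout_radius_km

    reason[near_colony] = "colony_radius"
    reason[shallow] = "shallow_depth"
    reason[tag] = "tag_flag"
    out["is_haulout"] = tag | shallow | near_colony
    out["haulout_reason"] = reason
    return out


@dataclass
class Trip:
    id: str
    animal_id: str
    number: int
    start: pd.Timestamp
    end: pd.Timestamp
    fixes: pd.DataFrame
    origin: tuple | None  # (lon, lat) of bounding haulout fix, None at stream edge
    destination: tuple | None
    complete: bool
    trip_type: str = "unclassified"

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).value / (24 * HOUR_NS)


def segment_trips(calls: pd.DataFrame, min_trip_hours: float = 24.0
                  ) -> tuple[list[Trip], list[pd.DataFrame]]:
    """Partition one animal's classified fixes into trips and short bouts.

    ``calls`` must be the time-sorted output of :func:`classify_haulout`
    for a single animal.  Returns (trips, excluded short at-sea bouts).
    """
    if len(calls) == 0:
        return [], []
    calls = calls.reset_index(drop=True)
    animal = str(calls["id"].iloc[0])
    is_h = calls["is_haulout"].to_numpy(bool)
    at_sea_idx = np.flatnonzero(~is_h)
    if at_sea_idx.size == 0:
        return [], []

    # maximal runs of consecutive at-sea fixes
    breaks = np.flatnonzero(np.diff(at_sea_idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [at_sea_idx.size - 1]])

    trips: list[Trip] = []
    excluded: list[pd.DataFrame] = []
    number = 0
    t = calls["time"]
    for rs, re_ in zip(run_starts, run_ends):
        i0, i1 = at_sea_idx[rs], at_sea_idx[re_]
        span_h = (t.iloc[i1] - t.iloc[i0]).value / HOUR_NS
        bout = calls.iloc[i0:i1 + 1]
        if span_h <= min_trip_hours:
            excluded.append(bout)
            continue
        number += 1
        origin = None
        if i0 > 0:
            origin = (float(calls["lon"].iloc[i0 - 1]), float(calls["lat"].iloc[i0 - 1]))
        destination = None
        complete = i1 < len(calls) - 1
        if complete:
            destination = (float(calls["lon"].iloc[i1 + 1]), float(calls["lat"].iloc[i1 + 1]))
        trips.append(Trip(
            id=f"{animal}-T{number:02d}", animal_id=animal, number=number,
            start=t.iloc[i0], end=t.iloc[i1], fixes=bout,
            origin=origin, destination=destination, complete=complete,
        ))
    return trips, excluded


def trip_metrics(trip: Trip, next_trip: Trip | None = None,
                 calls: pd.DataFrame | None = None) -> dict:
    """Duration (d), cumulative great-circle distance (km), mean speed (km/h),
    and the subsequent haulout duration (h) when a next trip exists.

    Haulout duration runs from the first hauled-out fix after the trip to
    the first at-sea fix of the next trip, per the fix-to-fix definition.
    """
    fx = trip.fixes
    duration_d = trip.duration_days
    if len(fx) >= 2:
        lon = fx["lon"].to_numpy(float)
        lat = fx["lat"].to_numpy(float)
        dist = float(np.sum(great_circle_distance(
            (lon[:-1], lat[:-1]), (lon[1:], lat[1:]))))
    else:
        dist = 0.0
    hours = duration_d * 24.0
    speed = dist / hours if hours > 0 and len(fx) >= 2 else np.nan

    haulout_h = np.nan
    if next_trip is not None and trip.complete and calls is not None:
        after = calls[(calls["time"] > trip.end) & calls["is_haulout"]]
        if len(after):
            haulout_h = (next_trip.start - after["time"].iloc[0]).value / HOUR_NS

    return {
        "trip_id": trip.id, "id": trip.animal_id, "number": trip.number,
        "start": trip.start, "end": trip.end, "complete": trip.complete,
        "duration_d": duration_d, "distance_km": dist, "speed_kmh": speed,
        "haulout_duration_h": haulout_h,
    }


def classify_trip_type(trip: Trip, colony: ColonyGeometry) -> str:
    """A: colony-to-colony; B: exactly one endpoint at the colony; C: neither."""
    if not trip.complete or trip.origin is None or trip.destination is None:
        return "incomplete"
    r = colony.haulout_radius_km
    o = colony.distance_km(*trip.origin) <= r
    d = colony.distance_km(*trip.destination) <= r
    if o and d:
        return "A"
    if o or d:
        return "B"
    return "C"


def build_trip_table(calls: pd.DataFrame, colony: ColonyGeometry) -> pd.DataFrame:
    """Segment every animal's classified fixes and tabulate complete-trip
    metrics plus types (one row per trip, S1-style columns)."""
    rows = []
    for animal, grp in calls.groupby("id", sort=False):
        trips, _ = segment_trips(grp)
        for j, trip in enumerate(trips):
            nxt = trips[j + 1] if j + 1 < len(trips) else None
            m = trip_metrics(trip, nxt, grp)
            m["trip_type"] = classify_trip_type(trip, colony)
            m["week_at_end"] = np.nan
            rows.append(m)
    df = pd.DataFrame(rows)
    if len(df):
        first_at_sea = {a: t for a, t in df.groupby("id")["start"].min().items()}
        df["week_at_end"] = [
            int(np.floor((row.end - first_at_sea[row.id]).value / (7 * 24 * HOUR_NS))) + 1
            for row in df.itertuples()
        ]
    return df


def derive_animal_covariates(pup_row: pd.Series | dict, trips: list[Trip],
                             deployment_days: float) -> dict:
    """Post-weaning duration, per-trip week labels, and trip frequency.

    postwean = first at-sea fix of the first trip minus the weaning date;
    week(t) = floor((t - first at-sea time) / 7 d) + 1; trip frequency =
    complete trips / deployment days.
    """
    pup = dict(pup_row)
    complete = [t for t in trips if t.complete]
    if not trips:
        return {"postwean_days": np.nan, "weeks": {},
                "trip_frequency": 0.0 if deployment_days > 0 else np.nan}
    first_at_sea = min(t.start for t in trips)
    postwean = np.nan
    if "wean_date" in pup and pd.notna(pup["wean_date"]):
        postwean = (first_at_sea - pd.Timestamp(pup["wean_date"])).value / (24 * HOUR_NS)
    weeks = {t.id: int(np.floor((t.end - first_at_sea).value / (7 * 24 * HOUR_NS))) + 1
             for t in trips}
    freq = len(complete) / deployment_days if deployment_days > 0 else np.nan
    return {"postwean_days": postwean, "weeks": weeks, "trip_frequency": freq}
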