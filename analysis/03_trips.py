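"""Classify haulouts and segment each pup's record into trips.

A fix is hauled out if the tag flagged it, the water column is <= 5 m, or
it lies within 10 km of the colony axis.  At-sea bouts longer than 24 h
become trips; each complete trip gets duration, cumulative distance, mean
speed, following-haulout duration, type (A colony-colony, B mixed,
C offshore-offshore) and the week at sea at trip end.
"""

from pathlib import Path

from puptrack.bathymetry import BathymetryGrid
from puptrack.qc import read_fixes
from puptrack.trips import ColonyGeometry, build_trip_table, classify_haulout

OUT = Path("results/analysis")


def main() -> None:
    bathy = BathymetryGrid.from_netcdf(OUT / "bathymetry.nc")
    kept = read_fixes(OUT / "fixes_qc.csv")
    colony = ColonyGeometry()

    calls = classify_haulout(kept, bathy, colony)
    calls.to_csv(OUT / "haulout_calls.csv", index=False)
    trips = build_trip_table(calls, colony)
    trips.to_csv(OUT / "trips.csv", index=False)

    complete = trips[trips["complete"]]
    types = complete["trip_type"].value_counts().to_dict()
    print(f"{len(trips)} trips, {len(complete)} complete; types {types}")
    print(f"duration {complete['duration_d'].mean():.1f} +/- "
          f"{complete['duration_d'].std():.1f} d, distance "
          f"{complete['distance_km'].mean():.0f} km, haulout "
          f"{complete['haulout_duration_h'].mean():.1f} h")


if __name__ == "__main__":
    main()
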