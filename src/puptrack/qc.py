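"""Fastloc GPS quality control.

Three filters, applied in a fixed order per animal:

1. satellite filter — drop fixes computed from fewer than ``min_satellites``
   satellites (default: fewer than five);
2. residual filter — drop fixes whose Fastloc residual error metric exceeds
   ``max_residual`` (default: strictly greater than 30);
3. speed filter — a single forward sweep over the survivors, dropping any
   fix whose great-circle speed from the last retained fix exceeds
   ``max_speed`` (default 10 km/h).

Each removed fix carries exactly one removal reason: the first filter that
rejected it.  The audit report satisfies
``n_input == n_kept + n_removed_satellites + n_removed_residual + n_removed_speed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

FIX_COLUMNS = ["id", "time", "lon", "lat", "n_sat", "residual", "tag_haulout"]


@dataclass
class QCConfig:
    min_satellites: int = 5
    max_residual: float = 30.0
    max_speed_kmh: float = 10.0
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if min(self.min_satellites, self.max_residual, self.max_speed_kmh,
               self.earth_radius_km) <= 0:
            raise ValueError("all QC thresholds must be > 0")


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_satellites: int = 0
    n_removed_residual: int = 0
    n_removed_speed: int = 0
    n_kept: int = 0
    removal_reason: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_satellites": self.n_removed_satellites,
            "n_removed_residual": self.n_removed_residual,
            "n_removed_speed": self.n_removed_speed,
            "n_kept": self.n_kept,
        }

    @property
    def consistent(self) -> bool:
        return self.n_input == (self.n_kept + self.n_removed_satellites
                                + self.n_removed_residual + self.n_removed_speed)


def great_circle_distance(a, b, earth_radius_km: float = EARTH_RADIUS_KM):
    """Haversine distance in km between (lon, lat) points in decimal degrees.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    lon1, lat1 = np.asarray(a[0], dtype=float), np.asarray(a[1], dtype=float)
    lon2, lat2 = np.asarray(b[0], dtype=float), np.asarray(b[1], dtype=float)
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * earth_radius_km * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _speed_sweep(df: pd.DataFrame, max_speed_kmh: float, earth_radius_km: float) -> np.ndarray:
    """Forward sweep: keep a fix iff its speed from the last retained fix is
    within the threshold. Returns boolean keep mask (first fix always kept)."""
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    t = df["time"].to_numpy("datetime64[ns]").astype("int64") / 3.6e12  # hours
    keep = np.ones(len(df), dtype=bool)
    if len(df) == 0:
        return keep
    last = 0
    for i in range(1, len(df)):
        dt = t[i] - t[last]
        dist = great_circle_distance((lon[last], lat[last]), (lon[i], lat[i]),
                                     earth_radius_km)
        if dt <= 0:
            # coincident timestamps: drop unless the position is identical
            if dist > 0:
                keep[i] = False
                continue
        elif dist / dt > max_speed_kmh:
            keep[i] = False
            continue
        last = i
    return keep


def filter_fixes(stream: pd.DataFrame, config: QCConfig | None = None
                 ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the three QC filters per animal; return kept fixes and an audit.

    The stream must be time-sorted within each animal id.  Order is
    preserved in the output.
    """
    config = config or QCConfig()
    stream = stream.reset_index(drop=True)
    report = QCReport(n_input=len(stream))
    if len(stream) == 0:
        report.removal_reason = pd.Series(dtype=object)
        return stream, report

    for _, grp in stream.groupby("id", sort=False):
        if not grp["time"].is_monotonic_increasing:
            raise ValueError("fix times must be sorted within each animal")

    reason = pd.Series(index=stream.index, dtype=object)
    bad_sat = stream["n_sat"].to_numpy() < config.min_satellites
    reason[bad_sat] = "satellites"
    bad_res = (~bad_sat) & (stream["residual"].to_numpy() > config.max_residual)
    reason[bad_res] = "residual"

    survivors = stream[reason.isna()]
    for _, grp in survivors.groupby("id", sort=False):
        keep = _speed_sweep(grp, config.max_speed_kmh, config.earth_radius_km)
        reason[grp.index[~keep]] = "speed"

    kept = stream[reason.isna()].copy()
    report.n_removed_satellites = int((reason == "satellites").sum())
    report.n_removed_residual = int((reason == "residual").sum())
    report.n_removed_speed = int((reason == "speed").sum())
    report.n_kept = len(kept)
    report.removal_reason = reason
    return kept, report


def read_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
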