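"""Synthetic shelf bathymetry: a sandbar island on a bank-and-basin shelf.

The grid emulates the structure of a continental shelf around an isolated
sandbar breeding colony: a long narrow island standing a few metres above
sea level, a surrounding shallow bank, a handful of offshore banks (30-60 m)
and basins (200-300 m), and a shelf break beyond which depth falls to
abyssal values (>= 1000 m).  Elevation follows the usual convention:
negative below sea level, metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0


class ConfigurationError(ValueError):
    """Raised when a simulation or grid configuration is invalid."""


@dataclass
class BankSpec:
    """A Gaussian shoaling feature. depth_m is the depth at the crest (30-60 m)."""

    lon: float
    lat: float
    depth_m: float
    radius_km: float = 40.0


@dataclass
class BasinSpec:
    """A Gaussian deepening feature. depth_m is the depth at the centre (200-300 m)."""

    lon: float
    lat: float
    depth_m: float
    radius_km: float = 50.0


@dataclass
class BathymetryConfig:
    lon_min: float = -63.0
    lon_max: float = -57.0
    lat_min: float = 41.5
    lat_max: float = 46.5
    cell_size: float = 0.02
    island_lon: float = -59.91
    island_lat: float = 43.93
    island_height_m: float = 3.0
    island_length_km: float = 43.0
    island_width_km: float = 1.5
    shelf_depth_m: float = 80.0
    shelf_break_radius_km: float = 320.0
    abyss_depth_m: float = 2500.0
    banks: list[BankSpec] = field(default_factory=lambda: [
        BankSpec(-60.5, 43.55, 35.0, 45.0),
        BankSpec(-58.9, 44.45, 55.0, 40.0),
        BankSpec(-61.9, 43.1, 45.0, 35.0),
    ])
    basins: list[BasinSpec] = field(default_factory=lambda: [
        BasinSpec(-61.3, 44.6, 260.0, 45.0),
        BasinSpec(-58.3, 43.2, 220.0, 40.0),
    ])
    # small exposed shoals on bank crests: non-colony haulout substrate
    skerries: list[BankSpec] = field(default_factory=lambda: [
        BankSpec(-58.72, 44.58, 2.0, 2.5),
        BankSpec(-62.05, 42.95, 2.0, 2.5),
    ])
    noise_sd_m: float = 1.5
    island_enabled: bool = True


@dataclass
class BathymetryGrid:
    """Elevation raster on a regular lon/lat lattice (metres, negative = below sea)."""

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    elevation: np.ndarray  # shape (nlat, nlon)
    cell_size: float

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.lon_axis) > 0) and np.all(np.diff(self.lat_axis) > 0)):
            raise ConfigurationError("grid axes must be strictly increasing")
        if not np.all(np.isfinite(self.elevation)):
            raise ConfigurationError("elevation must be finite everywhere")
        if self.elevation.shape != (self.lat_axis.size, self.lon_axis.size):
            raise ConfigurationError("elevation shape must be (nlat, nlon)")

    # ----- lookups -------------------------------------------------------

    def _indices(self, lon, lat):
        i = np.clip(np.searchsorted(self.lat_axis, np.asarray(lat)), 0, self.lat_axis.size - 1)
        j = np.clip(np.searchsorted(self.lon_axis, np.asarray(lon)), 0, self.lon_axis.size - 1)
        # searchsorted gives right neighbour; take the nearer of the two
        i = np.where(
            (i > 0)
            & (np.abs(np.asarray(lat) - self.lat_axis[np.maximum(i - 1, 0)])
               < np.abs(np.asarray(lat) - self.lat_axis[i])),
            i - 1, i,
        )
        j = np.where(
            (j > 0)
            & (np.abs(np.asarray(lon) - self.lon_axis[np.maximum(j - 1, 0)])
               < np.abs(np.asarray(lon) - self.lon_axis[j])),
            j - 1, j,
        )
        return i, j

    def contains(self, lon, lat):
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_axis[0]) & (lon <= self.lon_axis[-1])
            & (lat >= self.lat_axis[0]) & (lat <= self.lat_axis[-1])
        )

    def elevation_at(self, lon, lat):
        """Nearest-cell elevation (m) at the given coordinates."""
        i, j = self._indices(lon, lat)
        return self.elevation[i, j]

    def depth_at(self, lon, lat):
        """Water depth (m, positive down) = -elevation; negative over land."""
        return -self.elevation_at(lon, lat)

    def coastline_mask(self) -> np.ndarray:
        """Cells on the 0 m isobath: land cells (elevation >= 0) bordering sea."""
        land = self.elevation >= 0.0
        sea = ~land
        neighbour_sea = np.zeros_like(land)
        neighbour_sea[1:, :] |= sea[:-1, :]
        neighbour_sea[:-1, :] |= sea[1:, :]
        neighbour_sea[:, 1:] |= sea[:, :-1]
        neighbour_sea[:, :-1] |= sea[:, 1:]
        return land & neighbour_sea

    def coastline_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centres of the 0 m isobath cells."""
        ii, jj = np.nonzero(self.coastline_mask())
        return self.lon_axis[jj], self.lat_axis[ii]

    def shore_cells(self, max_depth_m: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
        """Centres of cells with depth <= max_depth_m (haulout-capable substrate)."""
        ii, jj = np.nonzero(-self.elevation <= max_depth_m)
        return self.lon_axis[jj], self.lat_axis[ii]

    # ----- IO ------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {"elevation": (("lat", "lon"), self.elevation)},
            coords={"lon": self.lon_axis, "lat": self.lat_axis},
            attrs={"convention": "elevation in metres, negative below sea level"},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "BathymetryGrid":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            lon = ds["lon"].values.astype(float)
            lat = ds["lat"].values.astype(float)
            elev = ds["elevation"].values.astype(float)
        return cls(lon, lat, elev, float(np.median(np.diff(lon))))

    def to_ascii_grid(self, path) -> None:
        """ESRI-ASCII export (row order north to south, as the format requires)."""
        header = (
            f"ncols {self.lon_axis.size}\n"
            f"nrows {self.lat_axis.size}\n"
            f"xllcorner {self.lon_axis[0] - self.cell_size / 2:.6f}\n"
            f"yllcorner {self.lat_axis[0] - self.cell_size / 2:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.elevation[::-1], fmt="%.2f")


def _km_offsets(lon, lat, lon0, lat0):
    """Equirectangular offsets (km) from (lon0, lat0), cos-latitude scaled."""
    kx = np.radians(lon - lon0) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    ky = np.radians(lat - lat0) * EARTH_RADIUS_KM
    return kx, ky


def make_bathymetry(config: BathymetryConfig | None = None, seed: int = 0) -> BathymetryGrid:
    """Deterministically generate the synthetic shelf grid.

    Construction guarantees: the island block has elevation > 0 (when
    enabled); bank crests sit at their configured 30-60 m depth; basin
    centres at 200-300 m; every cell beyond the shelf-break radius is at
    least 1000 m deep.
    """
    config = config or BathymetryConfig()
    if config.lon_max <= config.lon_min or config.lat_max <= config.lat_min:
        raise ConfigurationError("degenerate grid extent")
    if config.cell_size <= 0:
        raise ConfigurationError("cell_size must be > 0")

    lon = np.arange(config.lon_min, config.lon_max + config.cell_size / 2, config.cell_size)
    lat = np.arange(config.lat_min, config.lat_max + config.cell_size / 2, config.cell_size)
    glon, glat = np.meshgrid(lon, lat)
    kx, ky = _km_offsets(glon, glat, config.island_lon, config.island_lat)
    r = np.hypot(kx, ky)

    # shelf with additive bank/basin perturbations, ramping to the abyss
    # across the shelf break
    ramp = 1.0 / (1.0 + np.exp(-(r - config.shelf_break_radius_km) / 25.0))
    depth = config.shelf_depth_m + (config.abyss_depth_m - config.shelf_depth_m) * ramp

    for basin in config.basins:
        bx, by = _km_offsets(glon, glat, basin.lon, basin.lat)
        bump = np.exp(-(bx**2 + by**2) / (2 * basin.radius_km**2))
        depth = depth + (basin.depth_m - config.shelf_depth_m) * bump
    for bank in config.banks:
        bx, by = _km_offsets(glon, glat, bank.lon, bank.lat)
        bump = np.exp(-(bx**2 + by**2) / (2 * bank.radius_km**2))
        depth = depth + (bank.depth_m - config.shelf_depth_m) * bump

    rng = np.random.default_rng(seed)
    elev = -depth + rng.normal(0.0, config.noise_sd_m, depth.shape)
    for sk in config.skerries:
        bx, by = _km_offsets(glon, glat, sk.lon, sk.lat)
        inside = np.hypot(bx, by) <= sk.radius_km
        elev = np.where(inside, np.maximum(elev, -sk.depth_m), elev)

    if config.island_enabled:
        # crescent approximated as an east-west ellipse with a shoaling apron
        ix, iy = _km_offsets(glon, glat, config.island_lon, config.island_lat)
        cell_km = config.cell_size * np.pi / 180.0 * EARTH_RADIUS_KM
        # the sandbar is narrower than a raster cell; widen to the cell scale
        # so the island exists on the lattice
        a = max(config.island_length_km / 2.0, 1.05 * cell_km)
        b = max(config.island_width_km / 2.0, 1.05 * cell_km)
        core = (ix / a) ** 2 + (iy / b) ** 2
        apron = (ix / (a + 12.0)) ** 2 + (iy / (b + 12.0)) ** 2
        elev = np.where(apron < 1.0, np.maximum(elev, -30.0 * apron - 2.0), elev)
        elev = np.where(core < 1.0, config.island_height_m * (1.0 - core) + 0.5, elev)

    # hard guarantee beyond the shelf break
    beyond = r > config.shelf_break_radius_km + 50.0
    elev = np.where(beyond, np.minimum(elev, -1000.0), elev)

    return BathymetryGrid(lon, lat, elev, config.cell_size)
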