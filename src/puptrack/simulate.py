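"""Synthetic pup cohorts, latent movement, and Fastloc tag emulation.

The generative movement process is the same first-difference correlated
random walk the estimator assumes, run forward at the analysis time step
(default 6 h):

    d_t = gamma_t * d_{t-1} + eps_t,   eps_t ~ N(0, diag(sigma_step^2))
    logit(gamma_t) = x_t' beta + b_i,  b_i ~ N(0, sigma_b^2)

with covariates (sex, weaning mass and length, post-weaning duration, week
at sea, distance to shore, ln depth) computed from the synthetic bathymetry
and the pup's biometrics.  At-sea movement alternates with haulout windows
during which the animal is pinned to a shore cell (depth <= 5 m); during
the final approach to a scheduled haulout the walk is steered toward the
haulout site so that arrival is physically continuous.

The tag emulator then produces an irregular Fastloc fix stream: 15-minute
attempts thinned by a surfacing Bernoulli, suppression during haulouts
(with the 20-minute entry lag of the wet/dry logic), per-fix satellite
counts and residual draws, and occasional injected position outliers large
enough to violate a 10 km/h speed filter.  Ground truth (which fixes are
outliers, the latent gamma series, the haulout schedule) is recorded for
recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from puptrack.bathymetry import BathymetryGrid, ConfigurationError, EARTH_RADIUS_KM
from puptrack.qc import great_circle_distance

DAY_NS = 86_400 * 10**9

DEFAULT_BETA = {
    "intercept": 11.747,
    "sex_female": -0.452,
    "mass": 0.0151,
    "length": -0.105,
    "postwean": -0.0507,
    "week": -0.0355,
    "dist_shore": -0.00525,
    "ln_depth": 0.502,
}


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class PupRecord:
    id: str
    sex: str  # "male" | "female"
    mass_wean: float  # kg
    length_wean: float  # cm
    wean_date: pd.Timestamp
    postwean_days: float
    release_lon: float
    release_lat: float
    deployment_days: float = 90.0

    def __post_init__(self) -> None:
        if self.mass_wean <= 0 or self.length_wean <= 0:
            raise ConfigurationError("biometrics must be positive")
        if self.postwean_days < 0:
            raise ConfigurationError("postwean_days must be >= 0")

    @property
    def sex_code(self) -> int:
        """Tabular convention: male = 1, female = 2."""
        return 1 if self.sex == "male" else 2

    @property
    def departure(self) -> pd.Timestamp:
        return self.wean_date + pd.Timedelta(days=float(self.postwean_days))


@dataclass
class CohortParams:
    """Cohort-level biometric distributions (means/sds per sex, kg and cm)."""

    n_pups: int = 25
    male_fraction: float = 12 / 25
    mass_mean: dict = field(default_factory=lambda: {"male": 55.7, "female": 54.5})
    mass_sd: dict = field(default_factory=lambda: {"male": 4.74, "female": 6.31})
    length_mean: dict = field(default_factory=lambda: {"male": 112.0, "female": 111.2})
    length_sd: dict = field(default_factory=lambda: {"male": 3.38, "female": 2.37})
    mass_length_corr: float = 0.55
    postwean_mean: dict = field(default_factory=lambda: {"male": 23.9, "female": 19.1})
    postwean_sd: dict = field(default_factory=lambda: {"male": 4.25, "female": 6.56})
    deployment_mean_d: float = 82.7
    deployment_sd_d: float = 46.38
    deployment_range_d: tuple = (10.0, 175.0)
    wean_start: str = "2016-01-12"
    wean_span_days: int = 12
    release_lon: float = -59.91
    release_lat: float = 43.93


def simulate_cohort(params: CohortParams | None = None, seed: int = 0) -> list[PupRecord]:
    """Draw a pup cohort: bivariate-normal mass/length (configured correlation),
    truncated-normal post-weaning fast (>= 1 d), seeded and reproducible."""
    params = params or CohortParams()
    if params.n_pups < 1:
        raise ConfigurationError("n_pups must be >= 1")
    if not (-1.0 < params.mass_length_corr < 1.0):
        raise ConfigurationError("mass-length correlation must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    n_males = int(round(params.n_pups * params.male_fraction))
    sexes = ["male"] * n_males + ["female"] * (params.n_pups - n_males)
    rho = params.mass_length_corr
    wean0 = pd.Timestamp(params.wean_start)
    pups = []
    for i, sex in enumerate(sexes):
        z1, z2 = rng.standard_normal(2)
        length = params.length_mean[sex] + params.length_sd[sex] * z1
        mass = params.mass_mean[sex] + params.mass_sd[sex] * (
            rho * z1 + np.sqrt(1 - rho**2) * z2
        )
        mass = max(mass, 20.0)
        length = max(length, 80.0)
        pw = 0.0
        while pw < 1.0:
            pw = rng.normal(params.postwean_mean[sex], params.postwean_sd[sex])
        dep = -1.0
        lo, hi = params.deployment_range_d
        while not (lo <= dep <= hi):
            dep = rng.normal(params.deployment_mean_d, params.deployment_sd_d)
        pups.append(PupRecord(
            id=f"P{i + 1:03d}",
            sex=sex,
            mass_wean=round(float(mass) * 2) / 2,  # weighed to nearest 0.5 kg
            length_wean=round(float(length)),
            wean_date=wean0 + pd.Timedelta(days=int(rng.integers(0, params.wean_span_days + 1))),
            postwean_days=round(float(pw)),
            release_lon=params.release_lon,
            release_lat=params.release_lat,
            deployment_days=round(float(dep)),
        ))
    return pups


def cohort_frame(pups: list[PupRecord]) -> pd.DataFrame:
    rows = [{
        "id": p.id, "sex": p.sex, "sex_code": p.sex_code, "mass_wean": p.mass_wean,
        "length_wean": p.length_wean, "wean_date": p.wean_date,
        "postwean_days": p.postwean_days, "deployment_days": p.deployment_days,
        "release_lon": p.release_lon, "release_lat": p.release_lat,
    } for p in pups]
    return pd.DataFrame(rows)


@dataclass
class TrackParams:
    """Generative movement and haulout-behaviour parameters."""

    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_b: float = 0.2
    sigma_step_km: tuple = (2.0, 2.0)  # innovation sd per axis at the latent step
    step_minutes: float = 90.0
    trip_duration_mean_d: float = 8.0
    trip_duration_sd_d: float = 6.0
    haulout_duration_mean_h: float = 33.6
    haulout_duration_sd_h: float = 29.0
    min_haulout_h: float = 2.0
    p_colony_return: float = 0.6
    cruise_speed_kmh: float = 4.0
    start_gamma: float = 0.8


@dataclass
class TruthRecord:
    """Ground truth for one simulated animal."""

    id: str
    beta: dict
    sigma_b: float
    b_i: float
    sigma_step_km: tuple
    gamma_true: np.ndarray
    at_sea: np.ndarray
    haulout_schedule: list  # [(start, end), ...) half-open windows
    step_minutes: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_true, dtype=float)
        if g.size and not ((g > 0).all() and (g < 1).all()):
            raise ConfigurationError("gamma_true must lie strictly in (0, 1)")
        if self.sigma_b < 0 or min(self.sigma_step_km) <= 0:
            raise ConfigurationError("sigma_b >= 0 and sigma_step > 0 required")

    def to_json(self, path) -> None:
        obj = {
            "id": self.id, "beta": self.beta, "sigma_b": self.sigma_b,
            "b_i": self.b_i, "sigma_step_km": list(self.sigma_step_km),
            "gamma_true": np.asarray(self.gamma_true).tolist(),
            "at_sea": np.asarray(self.at_sea).astype(int).tolist(),
            "haulout_schedule": [[str(a), str(b)] for a, b in self.haulout_schedule],
            "step_minutes": self.step_minutes,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _lognormal_params(mean, sd):
    """Moment-match a lognormal to the given mean and sd."""
    v = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - v / 2.0, np.sqrt(v)


def _local_frame(lat0):
    kx = EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    ky = EARTH_RADIUS_KM
    return kx, ky


def simulate_track(
    pup: PupRecord,
    bathy: BathymetryGrid,
    params: TrackParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Run the latent movement process for one pup.

    Returns a path DataFrame (time, lon, lat, at_sea, gamma_true) at the
    model step and the TruthRecord.  Haulout windows pin the animal to a
    shore cell (depth <= 5 m).
    """
    params = params or TrackParams()
    if not bool(np.all(bathy.contains(pup.release_lon, pup.release_lat))):
        raise ConfigurationError("release site is off the bathymetry grid")

    rng = np.random.default_rng(seed)
    dt_h = params.step_minutes / 60.0
    n_steps = int(np.floor(pup.deployment_days * 24.0 / dt_h))
    t0 = pup.departure
    times = t0 + pd.to_timedelta(np.arange(n_steps) * params.step_minutes, unit="m")

    shore_lon, shore_lat = bathy.shore_cells(5.0)
    coast_lon, coast_lat = bathy.coastline_points()
    colony = (pup.release_lon, pup.release_lat)

    b_i = float(rng.normal(0.0, params.sigma_b)) if params.sigma_b > 0 else 0.0
    beta = params.beta
    sx, sy = params.sigma_step_km
    sex_female = 1.0 if pup.sex == "female" else 0.0

    # local planar frame about the release site
    kx, ky = _local_frame(pup.release_lat)

    def to_km(lon, lat):
        return (np.radians(lon - colony[0]) * kx, np.radians(lat - colony[1]) * ky)

    def to_lonlat(x, y):
        return (colony[0] + np.degrees(x / kx), colony[1] + np.degrees(y / ky))

    def covariate_eta(lon, lat, t):
        depth = float(bathy.depth_at(lon, lat))
        depth = max(depth, 1.0)
        if coast_lon.size:
            dshore = float(np.min(great_circle_distance(
                (lon, lat), (coast_lon, coast_lat))))
        else:
            dshore = 0.0
        week = int(np.floor((t - t0).value / (7 * DAY_NS))) + 1
        eta = (beta["intercept"] + beta["sex_female"] * sex_female
               + beta["mass"] * pup.mass_wean + beta["length"] * pup.length_wean
               + beta["postwean"] * pup.postwean_days + beta["week"] * week
               + beta["dist_shore"] * dshore + beta["ln_depth"] * np.log(depth))
        return eta + b_i

    # schedule trips and haulouts over the deployment
    mu_t, s_t = _lognormal_params(params.trip_duration_mean_d, params.trip_duration_sd_d)
    mu_h, s_h = _lognormal_params(params.haulout_duration_mean_h, params.haulout_duration_sd_h)

    lon = np.empty(n_steps)
    lat = np.empty(n_steps)
    gamma = np.empty(n_steps)
    at_sea = np.zeros(n_steps, dtype=bool)
    schedule: list[tuple[pd.Timestamp, pd.Timestamp]] = []

    pos = np.array(to_km(*colony))
    heading = rng.uniform(0, 2 * np.pi)
    d_prev = params.start_gamma * sx * np.array([np.cos(heading), np.sin(heading)])

    # shore cells away from the colony are candidate non-colony haulout sites
    shore_from_colony = great_circle_distance(colony, (shore_lon, shore_lat))
    away = shore_from_colony > 15.0

    state = "sea"
    trip_end_step = min(n_steps, max(2, int(round(
        rng.lognormal(mu_t, s_t) * 24.0 / dt_h))))
    target_km = None
    haulout_end_step = -1
    haulout_start_idx = None

    margin = 0.15  # degrees kept clear of the grid edge
    lon_lo, lon_hi = bathy.lon_axis[0] + margin, bathy.lon_axis[-1] - margin
    lat_lo, lat_hi = bathy.lat_axis[0] + margin, bathy.lat_axis[-1] - margin

    for i in range(n_steps):
        cur_lon, cur_lat = to_lonlat(*pos)
        gamma[i] = float(inv_logit(covariate_eta(cur_lon, cur_lat, times[i])))

        if state == "haulout":
            lon[i], lat[i] = cur_lon, cur_lat
            if i + 1 >= haulout_end_step:
                if haulout_start_idx is not None:
                    schedule.append((times[haulout_start_idx],
                                     times[min(i + 1, n_steps - 1)]))
                    haulout_start_idx = None
                state = "sea"
                trip_end_step = min(n_steps, i + 1 + max(2, int(round(
                    rng.lognormal(mu_t, s_t) * 24.0 / dt_h))))
                target_km = None
                d_prev = rng.normal(0.0, [sx, sy])
            continue

        at_sea[i] = True
        lon[i], lat[i] = cur_lon, cur_lat

        # choose the haulout target once the scheduled trip end nears
        if target_km is None:
            if (not away.any()) or rng.uniform() < params.p_colony_return:
                tgt = colony
            else:
                k = int(rng.choice(np.flatnonzero(away)))
                tgt = (float(shore_lon[k]), float(shore_lat[k]))
            target_km = np.array(to_km(*tgt))

        dist_home = float(np.hypot(*(target_km - pos)))
        homing = i >= trip_end_step

        if homing and dist_home <= 1.5 * params.cruise_speed_kmh * dt_h:
            # arrived: haul out
            pos = target_km.copy()
            lon[i], lat[i] = to_lonlat(*pos)
            at_sea[i] = False
            state = "haulout"
            haulout_start_idx = i
            dur_h = max(params.min_haulout_h, rng.lognormal(mu_h, s_h))
            haulout_end_step = i + max(1, int(round(dur_h / dt_h)))
            continue

        d = gamma[i] * d_prev + rng.normal(0.0, [sx, sy])
        if homing and dist_home > 0:
            # persistent homing: a drift toward the haulout site whose
            # stationary mean speed is the cruise speed, leaving the
            # innovation autocorrelation structure intact
            u_home = (target_km - pos) / dist_home
            d = d + (1.0 - gamma[i]) * params.cruise_speed_kmh * dt_h * u_home

        new_pos = pos + d
        nlon, nlat = to_lonlat(*new_pos)
        if not (lon_lo < nlon < lon_hi and lat_lo < nlat < lat_hi):
            d = -0.5 * d  # soft reflection at the domain edge
            new_pos = pos + d
        pos = new_pos
        d_prev = d

    if state == "haulout" and haulout_start_idx is not None:
        schedule.append((times[haulout_start_idx], times[n_steps - 1]))

    path = pd.DataFrame({
        "id": pup.id, "time": times, "lon": lon, "lat": lat,
        "at_sea": at_sea, "gamma_true": gamma,
    })
    truth = TruthRecord(
        id=pup.id, beta=dict(beta), sigma_b=params.sigma_b, b_i=b_i,
        sigma_step_km=tuple(params.sigma_step_km), gamma_true=gamma,
        at_sea=at_sea, haulout_schedule=schedule, step_minutes=params.step_minutes,
    )
    return path, truth


def simulate_model_cohort(n_animals: int = 22, n_steps: int = 260,
                          beta: dict | None = None, sigma_b: float = 0.2,
                          sigma_step_km: tuple = (4.0, 4.0), seed: int = 0,
                          tracks_per_animal: int = 1):
    """Generate model-scale data directly from the persistence process.

    Produces a ModelData whose design matrix carries realistic covariate
    distributions (biometrics at cohort scale; depth, distance to shore and
    week at the magnitudes typical of shelf movements) and whose
    displacements are drawn exactly from the first-difference CRW with
    logit-linked persistence.  Used for estimator validation: the data obey
    the model's own assumptions, so bias and coverage reflect the
    estimator, not the observation process.

    Returns (ModelData, truth dict with beta/sigma_b/b_i/gamma).
    """
    from puptrack.mpmm import COVARIATE_ORDER, ModelData

    beta = dict(DEFAULT_BETA) if beta is None else dict(beta)
    rng = np.random.default_rng(seed)
    cp = CohortParams()
    rows_d, rows_p, rows_X, rows_a, rows_k, gam_all = [], [], [], [], [], []
    b_all = []
    names = ["intercept"] + list(COVARIATE_ORDER)
    bvec = np.array([beta.get(n, 0.0) for n in names])
    track = 0
    for a in range(n_animals):
        sex = "male" if rng.uniform() < cp.male_fraction else "female"
        z1, z2 = rng.standard_normal(2)
        length = cp.length_mean[sex] + cp.length_sd[sex] * z1
        rho = cp.mass_length_corr
        mass = cp.mass_mean[sex] + cp.mass_sd[sex] * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        postwean = max(1.0, rng.normal(cp.postwean_mean[sex], cp.postwean_sd[sex]))
        b_i = rng.normal(0.0, sigma_b) if sigma_b > 0 else 0.0
        b_all.append(b_i)
        for _ in range(tracks_per_animal):
            m = n_steps + 2
            week = 1 + np.arange(m) // 28  # 6-h steps: 28 per week
            # habitat covariates follow mean-reverting excursions: depth and
            # distance to shore decorrelate over a few days as animals cross
            # banks and basins, so most of their variance is within-track
            phi = 0.9
            innov_sd = np.sqrt(1.0 - phi**2)
            z = np.empty(m)
            z[0] = rng.standard_normal()
            for t in range(1, m):
                z[t] = phi * z[t - 1] + innov_sd * rng.standard_normal()
            dist_shore = np.clip(90.0 + rng.normal(0, 15) + 55.0 * z, 0.0, 350.0)
            z2 = np.empty(m)
            z2[0] = rng.standard_normal()
            for t in range(1, m):
                z2[t] = phi * z2[t - 1] + innov_sd * rng.standard_normal()
            ln_depth = np.clip(np.log(110.0) + rng.normal(0, 0.2) + 0.6 * z2,
                               0.0, np.log(3000.0))
            X = np.column_stack([
                np.ones(m), np.full(m, 1.0 if sex == "female" else 0.0),
                np.full(m, mass), np.full(m, length), np.full(m, postwean),
                week.astype(float), dist_shore, ln_depth,
            ])
            eta = X @ bvec + b_i
            g = inv_logit(eta)
            sx, sy = sigma_step_km
            d = np.zeros((m, 2))
            d[0] = rng.normal(0.0, [sx, sy]) / np.sqrt(1 - min(g[0], 0.99)**2)
            for t in range(1, m):
                d[t] = g[t] * d[t - 1] + rng.normal(0.0, [sx, sy])
            rows_d.append(d[1:])
            rows_p.append(d[:-1])
            rows_X.append(X[1:])
            rows_a.append(np.full(m - 1, a))
            rows_k.append(np.full(m - 1, track))
            gam_all.append(g[1:])
            track += 1
    md = ModelData(
        d=np.concatenate(rows_d), p=np.concatenate(rows_p),
        X=np.concatenate(rows_X), colnames=names,
        animal_idx=np.concatenate(rows_a).astype(int),
        animal_ids=[f"S{i + 1:03d}" for i in range(n_animals)],
        track_idx=np.concatenate(rows_k).astype(int),
    )
    truth = {"beta": beta, "sigma_b": sigma_b, "b_i": b_all,
             "sigma_step_km": tuple(sigma_step_km),
             "gamma": np.concatenate(gam_all)}
    return md, truth


@dataclass
class TagParams:
    """Fastloc tag artifact model."""

    attempt_minutes: float = 15.0
    p_surface: float = 0.6
    haulout_entry_lag_min: float = 20.0
    n_sat_values: tuple = (4, 5, 6, 7, 8, 9, 10, 11)
    n_sat_weights: tuple = (0.08, 0.10, 0.14, 0.17, 0.17, 0.14, 0.12, 0.08)
    residual_mean: float = 8.0
    outlier_rate: float = 0.02
    outlier_speed_factor: tuple = (1.5, 4.0)  # x the speed threshold over the local gap
    speed_threshold_kmh: float = 10.0
    battery_life_days: float | None = None  # None: the whole path

    def __post_init__(self) -> None:
        if self.battery_life_days is not None and self.battery_life_days <= 0:
            raise ConfigurationError("battery life must be > 0")


def emulate_tag(path: pd.DataFrame, params: TagParams | None = None, seed: int = 0
                ) -> tuple[pd.DataFrame, dict]:
    """Generate a RawFix stream from a latent path.

    Returns (fixes, truth_links) where truth_links records the indices of
    injected outliers and of low-quality (satellite/residual) fixes.
    Within-haulout attempts after the 20-minute wet/dry entry lag are
    suppressed; the entry-boundary fix carries tag_haulout = True.
    """
    params = params or TagParams()
    rng = np.random.default_rng(seed)

    t_ns = path["time"].to_numpy("datetime64[ns]").astype("int64")
    t0, t1 = t_ns[0], t_ns[-1]
    if params.battery_life_days is not None:
        t1 = min(t1, t0 + int(params.battery_life_days * DAY_NS))
    step_ns = int(params.attempt_minutes * 60 * 10**9)
    attempts = np.arange(t0, t1 + 1, step_ns)

    lon = np.interp(attempts, t_ns, path["lon"].to_numpy())
    lat = np.interp(attempts, t_ns, path["lat"].to_numpy())
    at_sea = np.interp(attempts, t_ns, path["at_sea"].to_numpy(float)) >= 1.0

    # haulout windows from the latent at-sea flag
    flag = (~at_sea).astype(int)
    starts = np.flatnonzero(np.diff(np.concatenate([[0], flag])) == 1)
    ends = np.flatnonzero(np.diff(np.concatenate([flag, [0]])) == -1) + 1

    keep = rng.uniform(size=attempts.size) < params.p_surface
    tag_haulout = np.zeros(attempts.size, dtype=bool)
    lag_ns = int(params.haulout_entry_lag_min * 60 * 10**9)
    for s, e in zip(starts, ends):
        win = attempts[s:e]
        inside = win > attempts[s] + lag_ns
        keep[s:e][inside] = False          # suppressed once the tag is dry
        keep[s:e][~inside] = True          # entry boundary fix(es) transmitted
        tag_haulout[s:e][~inside] = True

    idx = np.flatnonzero(keep)
    f_lon, f_lat = lon[idx].copy(), lat[idx].copy()
    f_t = attempts[idx]

    # outliers on at-sea fixes, displaced to violate the speed filter over
    # the realized gap to the neighbouring fixes
    outlier_mask = (rng.uniform(size=idx.size) < params.outlier_rate) & at_sea[idx]
    gaps_h = np.diff(f_t) / 3.6e12
    for k in np.flatnonzero(outlier_mask):
        g_prev = gaps_h[k - 1] if k > 0 else params.attempt_minutes / 60.0
        g_next = gaps_h[k] if k < gaps_h.size else params.attempt_minutes / 60.0
        gap = max(g_prev, g_next, params.attempt_minutes / 60.0)
        disp_km = params.speed_threshold_kmh * gap * rng.uniform(*params.outlier_speed_factor)
        theta = rng.uniform(0, 2 * np.pi)
        f_lat[k] += np.degrees(disp_km * np.sin(theta) / EARTH_RADIUS_KM)
        f_lon[k] += np.degrees(disp_km * np.cos(theta)
                               / (EARTH_RADIUS_KM * np.cos(np.radians(f_lat[k]))))

    n_sat = rng.choice(params.n_sat_values, size=idx.size,
                       p=np.asarray(params.n_sat_weights) / np.sum(params.n_sat_weights))
    residual = rng.exponential(params.residual_mean, size=idx.size)

    fixes = pd.DataFrame({
        "id": path["id"].iloc[0],
        "time": pd.to_datetime(f_t),
        "lon": f_lon,
        "lat": f_lat,
        "n_sat": n_sat.astype(int),
        "residual": residual,
        "tag_haulout": tag_haulout[idx],
    })
    links = {
        "outlier_idx": np.flatnonzero(outlier_mask).tolist(),
        "low_sat_idx": np.flatnonzero(n_sat < 5).tolist(),
        "high_residual_idx": np.flatnonzero(residual > 30.0).tolist(),
    }
    return fixes, links


def simulate_study(
    bathy: BathymetryGrid,
    cohort_params: CohortParams | None = None,
    track_params: TrackParams | None = None,
    tag_params: TagParams | None = None,
    seed: int = 0,
) -> dict:
    """Convenience end-to-end generator: cohort, latent paths, fix streams.

    Returns a dict with keys cohort (DataFrame), pups, paths, truths,
    fixes (concatenated DataFrame), links (per-pup truth linkage).
    Seeds for per-animal streams are derived from the master seed.
    """
    ss = np.random.SeedSequence(seed)
    pups = simulate_cohort(cohort_params, seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    child = ss.spawn(2 * len(pups))
    paths, truths, fixes, links = [], [], [], {}
    for i, pup in enumerate(pups):
        s1 = int(child[2 * i].generate_state(1)[0] % 2**31)
        s2 = int(child[2 * i + 1].generate_state(1)[0] % 2**31)
        path, truth = simulate_track(pup, bathy, track_params, seed=s1)
        fx, lk = emulate_tag(path, tag_params, seed=s2)
        paths.append(path)
        truths.append(truth)
        fixes.append(fx)
        links[pup.id] = lk
    return {
        "cohort": cohort_frame(pups),
        "pups": pups,
        "paths": paths,
        "truths": truths,
        "fixes": pd.concat(fixes, ignore_index=True),
        "links": links,
    }
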