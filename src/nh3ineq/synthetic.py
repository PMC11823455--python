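"""Self-contained synthetic scenes with the statistical structure the
analysis assumes.

A scene emulates a region where clustered point sources (permitted animal
facilities) sit on a uniform tropospheric background. The truth column field
is isotropic exponential decay per facility, additive across facilities:

    truth(x) = background + sum_f strength_f * exp(-d_f(x) / L)

with ``L`` the e-folding decay length — a statistical stand-in for the
observed exponential downfield gradients, not a dispersion model. Block
groups tessellate the region; their demographic composition is tied to
source proximity through a logistic link (slope = ``proximity_bias``) so
that non-reference-group population shares increase toward facilities.
Populations are deterministic expected counts (share x lognormal total),
which keeps the zero-bias scene exactly symmetric across groups and scene
generation a pure function of (config, seed).

Satellite sampling is emulated by footprints with random centres, nadir-like
12 km nominal diameter elongating off-nadir, footprint-averaged truth
columns, multiplicative Gaussian retrieval noise, and random cloud /
sensitivity quality fields. Per-day truth is modulated by meteorology so the
stratified analyses have a known truth: hot days (above the median morning
temperature) scale source strengths by ``hot_source_multiplier``, calm days
(at or below the median morning wind) scale the decay length by
``calm_decay_multiplier``.

The scene's ``designed_inequality`` records, per group, the relative and
absolute inequality obtained by running the noise-free truth field — as seen
through the observation operator — through the downstream machinery
(tenth-percentile background, enhancement, area-weighted aggregation,
population weighting). "As seen" matters: long-term averages of >= 12 km
footprints regridded with a smooth spatial response are a smoothed image of
the truth, and the smoothing is part of the estimator, so the oracle a
pipeline run can recover is the inequality of the smoothed field. It is
computed deterministically by convolving the truth grid with the expected
composite kernel (footprint average followed by response weighting, averaged
over footprint elongations and orientations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .enhancement import compute_background, compute_enhancement
from .geo import KM_PER_DEG_LAT, haversine_km, km_per_deg_lon
from .inequality import BlockGroups, aggregate_blockgroups, inequality_table
from .oversampling import GridSpec, OversampledGrid, PIXEL_COLUMNS

NOMINAL_SEMI_AXIS_KM = 6.0  # circular 12 km diameter footprint at nadir


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    ``region_bounds`` is (lat_min, lat_max, lon_min, lon_max) in decimal
    degrees. ``emission_strength_range`` is the column enhancement at the
    source (molecules cm^-2); ``background_column`` uses the magnitude of
    the real-record regional background (3.8e15 molecules cm^-2).
    ``base_shares`` are region-mean population shares for the non-reference
    groups (defaults follow the study region's reported means); the
    reference group takes the remainder.
    """

    region_bounds: tuple = (34.5, 35.5, -78.5, -77.5)
    n_facilities: int = 30
    n_facility_clusters: int = 5
    facility_cluster_sd_km: float = 15.0
    emission_strength_range: tuple = (5e15, 2e16)
    decay_length_km: float = 5.0
    background_column: float = 3.8e15
    demographic_groups: tuple = ("black", "hispanic", "american_indian", "white_nh")
    reference_group: str = "white_nh"
    base_shares: dict = field(
        default_factory=lambda: {"black": 0.25, "hispanic": 0.10, "american_indian": 0.02}
    )
    proximity_bias: float = 0.5
    blockgroup_grid_n: int = 20
    total_population_mean: float = 1200.0
    total_population_log_sd: float = 0.5
    hot_source_multiplier: float = 1.5
    calm_decay_multiplier: float = 1.5
    grid_spacing_deg: float = 0.01
    seed: int = 0

    def __post_init__(self):
        lat_min, lat_max, lon_min, lon_max = self.region_bounds
        if not (lat_max > lat_min and lon_max > lon_min):
            raise ValueError("degenerate region bounds")
        if self.decay_length_km <= 0:
            raise ValueError("decay_length_km must be positive")
        if self.background_column < 0:
            raise ValueError("background_column must be non-negative")
        if self.proximity_bias < 0:
            raise ValueError("proximity_bias must be non-negative")
        if self.n_facilities == 0 and self.proximity_bias > 0:
            raise ValueError("proximity_bias > 0 requires at least one facility")
        if self.reference_group not in self.demographic_groups:
            raise ValueError("reference group must be one of demographic_groups")
        if sum(self.base_shares.values()) >= 1.0:
            raise ValueError("non-reference base shares must sum below 1")


@dataclass
class SyntheticScene:
    """A generated scene: truth field, sources, regions, people, oracle."""

    config: SceneConfig
    facilities: pd.DataFrame
    blockgroups: BlockGroups
    demographics: pd.DataFrame
    designed_inequality: dict

    def truth_field(self, lat, lon, source_scale: float = 1.0, decay_scale: float = 1.0):
        """True column (molecules cm^-2) at arbitrary points.

        ``source_scale`` multiplies all source strengths (hot-day
        modulation); ``decay_scale`` multiplies the decay length (calm-day
        modulation).
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        out = np.full(lat.shape, self.config.background_column, dtype=float)
        if len(self.facilities):
            d = haversine_km(
                lat[..., None],
                lon[..., None],
                self.facilities["lat"].to_numpy(),
                self.facilities["lon"].to_numpy(),
            )
            length = self.config.decay_length_km * decay_scale
            strengths = self.facilities["strength"].to_numpy() * source_scale
            out = out + np.sum(strengths * np.exp(-d / length), axis=-1)
        return out


def _tessellate(config: SceneConfig) -> BlockGroups:
    lat_min, lat_max, lon_min, lon_max = config.region_bounds
    n = config.blockgroup_grid_n
    lat_edges = np.linspace(lat_min, lat_max, n + 1)
    lon_edges = np.linspace(lon_min, lon_max, n + 1)
    ids, polys = [], []
    for i in range(n):
        for j in range(n):
            ids.append(f"bg_{i:03d}_{j:03d}")
            polys.append(box(lon_edges[j], lat_edges[i], lon_edges[j + 1], lat_edges[i + 1]))
    return BlockGroups(ids, polys)


def _place_facilities(config: SceneConfig, rng: np.random.Generator) -> pd.DataFrame:
    lat_min, lat_max, lon_min, lon_max = config.region_bounds
    if config.n_facilities == 0:
        return pd.DataFrame(
            columns=["id", "lat", "lon", "type", "allowable_count", "strength"]
        )
    # cluster centres drawn from the inner 80% so clusters stay in-region
    pad_lat = 0.1 * (lat_max - lat_min)
    pad_lon = 0.1 * (lon_max - lon_min)
    n_cl = max(1, min(config.n_facility_clusters, config.n_facilities))
    c_lat = rng.uniform(lat_min + pad_lat, lat_max - pad_lat, n_cl)
    c_lon = rng.uniform(lon_min + pad_lon, lon_max - pad_lon, n_cl)
    which = rng.integers(0, n_cl, config.n_facilities)
    mid_lat = 0.5 * (lat_min + lat_max)
    sd_lat = config.facility_cluster_sd_km / KM_PER_DEG_LAT
    sd_lon = config.facility_cluster_sd_km / km_per_deg_lon(mid_lat)
    lat = np.clip(c_lat[which] + rng.normal(0, sd_lat, config.n_facilities), lat_min, lat_max)
    lon = np.clip(c_lon[which] + rng.normal(0, sd_lon, config.n_facilities), lon_min, lon_max)
    lo, hi = config.emission_strength_range
    strength = rng.uniform(lo, hi, config.n_facilities)
    return pd.DataFrame(
        {
            "id": [f"fac_{i:04d}" for i in range(config.n_facilities)],
            "lat": lat,
            "lon": lon,
            "type": "swine",
            "allowable_count": np.round(strength / 2e12).astype(int),
            "strength": strength,
        }
    )


def _demographics(
    config: SceneConfig, blockgroups: BlockGroups, facilities: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    centroids = blockgroups.centroids
    if len(facilities):
        d = haversine_km(
            centroids["lat"].to_numpy()[:, None],
            centroids["lon"].to_numpy()[:, None],
            facilities["lat"].to_numpy()[None, :],
            facilities["lon"].to_numpy()[None, :],
        ).min(axis=1)
        scale = d.std(ddof=0)
        z = (np.median(d) - d) / (scale if scale > 0 else 1.0)
    else:
        z = np.zeros(len(blockgroups))
    # logistic link: at zero bias every block group sits at the base shares
    f = 1.0 / (1.0 + np.exp(-config.proximity_bias * z))
    nonref = [g for g in config.demographic_groups if g != config.reference_group]
    shares = {g: 2.0 * config.base_shares[g] * f for g in nonref}
    total_nonref = np.sum(list(shares.values()), axis=0)
    over = total_nonref > 0.95
    if over.any():
        for g in nonref:
            shares[g] = np.where(over, shares[g] * 0.95 / total_nonref, shares[g])
        total_nonref = np.minimum(total_nonref, 0.95)
    shares[config.reference_group] = 1.0 - total_nonref

    mu = np.log(config.total_population_mean) - 0.5 * config.total_population_log_sd**2
    totals = rng.lognormal(mu, config.total_population_log_sd, len(blockgroups))
    rows = []
    for g in config.demographic_groups:
        for bg_id, s, t in zip(blockgroups.ids, shares[g], totals):
            rows.append({"blockgroup_id": bg_id, "group": g, "population": s * t})
    return pd.DataFrame(rows)


_KERNEL_VARIANTS = tuple(
    (0.25 if e == 0 else 0.75, o) for e in range(2) for o in (0.0, 45.0, 90.0, 135.0)
)


def _kernel_grid(spacing_deg: float, mid_lat: float, half: int):
    sx = spacing_deg * km_per_deg_lon(mid_lat)  # cell size, km east
    sy = spacing_deg * KM_PER_DEG_LAT  # cell size, km north
    n = 2 * half + 1
    de = (np.arange(n) - half)[None, :] * sx
    dn = (np.arange(n) - half)[:, None] * sy
    return sx, sy, de, dn


def _response_kernel(spacing_deg: float, mid_lat: float, k: float) -> np.ndarray:
    """Regridding response kernel, averaged over footprint variants."""
    a_max = 2.0 * NOMINAL_SEMI_AXIS_KM
    reach_km = a_max * (np.log(1e4) / np.log(2.0)) ** (1.0 / k) * np.sqrt(2.0)
    sx = spacing_deg * km_per_deg_lon(mid_lat)
    sy = spacing_deg * KM_PER_DEG_LAT
    half = int(np.ceil(reach_km / min(sx, sy)))
    _, _, de, dn = _kernel_grid(spacing_deg, mid_lat, half)
    kernel = np.zeros((2 * half + 1, 2 * half + 1))
    for elong, orient in _KERNEL_VARIANTS:
        a = NOMINAL_SEMI_AXIS_KM * (1.0 + elong)
        b = NOMINAL_SEMI_AXIS_KM
        theta = np.deg2rad(orient)
        u = de * np.sin(theta) + dn * np.cos(theta)
        v = de * np.cos(theta) - dn * np.sin(theta)
        resp = np.exp(-np.log(2.0) * (np.abs(u / a) ** k + np.abs(v / b) ** k))
        resp[resp < 1e-4] = 0.0
        kernel += resp / resp.sum()
    return kernel / kernel.sum()


def _footprint_kernel(spacing_deg: float, mid_lat: float) -> np.ndarray:
    """Footprint-averaging kernel (quadrature deposit) over variants."""
    a_max = 2.0 * NOMINAL_SEMI_AXIS_KM
    sx = spacing_deg * km_per_deg_lon(mid_lat)
    sy = spacing_deg * KM_PER_DEG_LAT
    half = int(np.ceil(a_max / min(sx, sy))) + 1
    n = 2 * half + 1
    kernel = np.zeros((n, n))
    for elong, orient in _KERNEL_VARIANTS:
        a = NOMINAL_SEMI_AXIS_KM * (1.0 + elong)
        b = NOMINAL_SEMI_AXIS_KM
        theta = np.deg2rad(orient)
        fp = np.zeros((n, n))
        qe = _QUAD[:, 0] * a * np.sin(theta) + _QUAD[:, 1] * b * np.cos(theta)
        qn = _QUAD[:, 0] * a * np.cos(theta) - _QUAD[:, 1] * b * np.sin(theta)
        fe = qe / sx + half
        fn = qn / sy + half
        j0 = np.floor(fe).astype(int)
        i0 = np.floor(fn).astype(int)
        we = fe - j0
        wn = fn - i0
        for ii, jj, wwn, wwe in zip(i0, j0, wn, we):
            fp[ii, jj] += (1 - wwn) * (1 - wwe)
            fp[ii, jj + 1] += (1 - wwn) * wwe
            fp[ii + 1, jj] += wwn * (1 - wwe)
            fp[ii + 1, jj + 1] += wwn * wwe
        kernel += fp / fp.sum()
    return kernel / kernel.sum()


def observed_truth_grid(
    scene: SyntheticScene,
    grid: GridSpec | None = None,
    k: float = 2.0,
    source_scale: float = 1.0,
    decay_scale: float = 1.0,
    heteroscedastic: bool = True,
) -> OversampledGrid:
    """Noise-free truth field as the oversampling estimator would see it.

    Two-stage dense-sampling limit: the truth is footprint-averaged, then
    regridded with the response kernel. With ``heteroscedastic`` weighting
    (uncertainties proportional to the column, the pipeline's observation
    model) the limit of the inverse-variance weighted mean at a cell is the
    ratio ``(S * C^-1) / (S * C^-2)`` over footprint-averaged columns ``C``
    — a harmonic-type mean that sits slightly below the plain kernel average
    wherever the field varies within the response support. With
    ``heteroscedastic=False`` (equal uncertainties) it is the plain
    convolution ``S * C``.
    """
    from scipy.signal import fftconvolve

    cfg = scene.config
    if grid is None:
        grid = GridSpec.from_bounds(*cfg.region_bounds, spacing_deg=cfg.grid_spacing_deg)
    mid_lat = grid.lat0 + grid.spacing_deg * (grid.n_lat - 1) / 2.0
    resp = _response_kernel(grid.spacing_deg, mid_lat, k=k)
    fp = _footprint_kernel(grid.spacing_deg, mid_lat)
    half = resp.shape[0] // 2 + fp.shape[0] // 2
    lats = grid.lat0 + grid.spacing_deg * (np.arange(grid.n_lat + 2 * half) - half)
    lons = grid.lon0 + grid.spacing_deg * (np.arange(grid.n_lon + 2 * half) - half)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    truth = scene.truth_field(
        glat.ravel(), glon.ravel(), source_scale=source_scale, decay_scale=decay_scale
    ).reshape(glat.shape)
    col = fftconvolve(truth, fp, mode="same")  # footprint-averaged columns
    if heteroscedastic and np.all(col > 0):
        num = fftconvolve(1.0 / col, resp, mode="same")
        den = fftconvolve(1.0 / col**2, resp, mode="same")
        smoothed = (num / den)[half:-half, half:-half]
    else:
        smoothed = fftconvolve(col, resp, mode="same")[half:-half, half:-half]
    return OversampledGrid(
        values=smoothed,
        total_weight=np.ones_like(smoothed),
        n_contrib=np.ones(smoothed.shape, dtype=np.int64),
        valid_mask=np.ones(smoothed.shape, dtype=bool),
        grid=grid,
        response_exponent=float(k),
    )


def _designed_inequality(scene: SyntheticScene) -> dict:
    """Run the observation-smoothed noise-free truth through the pipeline."""
    cfg = scene.config
    if len(scene.facilities) == 0:
        # constant field: no enhancements anywhere, no designed structure
        return {
            g: {"relative_pct": 0.0, "absolute": 0.0, "sem_abs": 0.0,
                "pw_mean_group": 0.0, "pw_mean_ref": 0.0}
            for g in cfg.demographic_groups
            if g != cfg.reference_group
        }
    ogrid = observed_truth_grid(scene)
    bg = compute_background(ogrid, percentile=10.0, period_label="designed")
    table = aggregate_blockgroups(compute_enhancement(ogrid, bg), scene.blockgroups)
    ineq = inequality_table(
        table, scene.demographics, cfg.demographic_groups, cfg.reference_group
    )
    return {
        row["group"]: {
            "relative_pct": float(row["relative"]),
            "absolute": float(row["absolute"]),
            "sem_abs": float(row["sem_abs"]),
            "pw_mean_group": float(row["pw_mean_group"]),
            "pw_mean_ref": float(row["pw_mean_ref"]),
        }
        for _, row in ineq.iterrows()
    }


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Build a scene deterministically from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    facilities = _place_facilities(config, rng)
    blockgroups = _tessellate(config)
    demographics = _demographics(config, blockgroups, facilities, rng)
    scene = SyntheticScene(
        config=config,
        facilities=facilities,
        blockgroups=blockgroups,
        demographics=demographics,
        designed_inequality={},
    )
    scene.designed_inequality = _designed_inequality(scene)
    return scene


def generate_meteorology(
    n_days: int,
    seed: int,
    wind_mean: float = 3.0,
    wind_log_sd: float = 0.5,
    temp_mean: float = 24.0,
    temp_sd: float = 4.0,
    precip_mean_mm: float = 0.14,
    start: str = "2016-04-01",
) -> pd.DataFrame:
    """Daily morning-mean station meteorology.

    Wind speeds are lognormal with the requested arithmetic mean (default
    3 m s^-1, the regional warm-season mean); temperatures are normal
    (default 24 degC); daily precipitation is exponential (default mean
    0.14 mm). Setting a spread parameter to zero produces identical values
    on every day (a degenerate series on which a median split must fail).
    """
    if n_days < 2:
        raise ValueError("need at least two days (median split undefined)")
    rng = np.random.default_rng(seed)
    if wind_log_sd > 0:
        mu = np.log(wind_mean) - 0.5 * wind_log_sd**2
        wind = rng.lognormal(mu, wind_log_sd, n_days)
    else:
        wind = np.full(n_days, wind_mean)
    temp = rng.normal(temp_mean, temp_sd, n_days) if temp_sd > 0 else np.full(n_days, temp_mean)
    precip = rng.exponential(precip_mean_mm, n_days) if precip_mean_mm > 0 else np.zeros(n_days)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n_days, freq="D"),
            "wind": wind,
            "temp": temp,
            "precip": precip,
        }
    )


# unit-disk quadrature offsets (fractions of the semi-axes) used to
# footprint-average the truth field; includes the centre point
_QUAD = np.array(
    [(u, v) for u in np.linspace(-0.8, 0.8, 5) for v in np.linspace(-0.8, 0.8, 5) if u * u + v * v <= 1.0]
)


def day_modulation(met: pd.DataFrame, config: SceneConfig) -> pd.DataFrame:
    """Per-day truth modulation factors implied by the meteorology.

    Hot days (strictly above the median temperature) get the source-strength
    multiplier; calm days (at or below the median wind, the same tie rule as
    the downstream median split) get the decay-length multiplier. A met
    variable with fewer than two distinct values leaves its factor at 1.
    """
    n = len(met)
    source_scale = np.ones(n)
    decay_scale = np.ones(n)
    temps = met["temp"].to_numpy(dtype=float)
    winds = met["wind"].to_numpy(dtype=float)
    if np.unique(temps).size >= 2:
        source_scale[temps > np.median(temps)] = config.hot_source_multiplier
    if np.unique(winds).size >= 2:
        decay_scale[winds <= np.median(winds)] = config.calm_decay_multiplier
    return pd.DataFrame(
        {"date": met["date"].to_numpy(), "source_scale": source_scale, "decay_scale": decay_scale}
    )


def simulate_columns(
    scene: SyntheticScene,
    met: pd.DataFrame,
    pixels_per_day: int,
    noise_cv: float,
    seed: int,
    platform: str = "A",
    p_sensitivity_ok: float = 0.9,
    cloud_beta: tuple = (0.8, 4.0),
    nominal_uncertainty: float = 1e14,
) -> pd.DataFrame:
    """Simulate Level-2-like morning soundings over the scene.

    Each sounding has a uniform-random centre, a footprint elongated
    off-nadir (semi-major up to twice the 6 km nadir semi-axis), a column
    equal to the footprint-averaged truth times ``1 + N(0, noise_cv)``, a
    reported 1-sigma uncertainty of ``noise_cv x`` the noise-free column
    (a fixed nominal value when ``noise_cv = 0``), and random cloud-fraction
    / sensitivity quality fields. Deterministic under ``seed``.
    """
    if len(met) == 0:
        raise ValueError("met record list is empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = scene.config.region_bounds
    mod = day_modulation(met, scene.config)

    frames = []
    for _, day in mod.iterrows():
        n = pixels_per_day
        lat = rng.uniform(lat_min, lat_max, n)
        lon = rng.uniform(lon_min, lon_max, n)
        elong = rng.uniform(0.0, 1.0, n)
        semi_major = NOMINAL_SEMI_AXIS_KM * (1.0 + elong)
        semi_minor = np.full(n, NOMINAL_SEMI_AXIS_KM)
        orient = rng.uniform(0.0, 180.0, n)

        theta = np.deg2rad(orient)
        du = _QUAD[:, 0][None, :] * semi_major[:, None]  # km along major axis
        dv = _QUAD[:, 1][None, :] * semi_minor[:, None]  # km along minor axis
        de_km = du * np.sin(theta)[:, None] + dv * np.cos(theta)[:, None]
        dn_km = du * np.cos(theta)[:, None] - dv * np.sin(theta)[:, None]
        qlat = lat[:, None] + dn_km / KM_PER_DEG_LAT
        qlon = lon[:, None] + de_km / km_per_deg_lon(lat)[:, None]
        truth = scene.truth_field(
            qlat.ravel(), qlon.ravel(),
            source_scale=day["source_scale"], decay_scale=day["decay_scale"],
        ).reshape(qlat.shape)
        fp_mean = truth.mean(axis=1)

        if noise_cv > 0:
            column = fp_mean * (1.0 + rng.normal(0.0, noise_cv, n))
            sigma = noise_cv * fp_mean
            sigma = np.where(sigma > 0, sigma, nominal_uncertainty)
        else:
            column = fp_mean
            sigma = np.full(n, nominal_uncertainty)

        frames.append(
            pd.DataFrame(
                {
                    "time": pd.Timestamp(day["date"]) + pd.Timedelta(hours=9, minutes=30),
                    "lat": lat,
                    "lon": lon,
                    "semi_major_km": semi_major,
                    "semi_minor_km": semi_minor,
                    "orientation_deg": orient,
                    "column": column,
                    "uncertainty": sigma,
                    "cloud_fraction": rng.beta(*cloud_beta, n),
                    "sensitivity_ok": rng.uniform(0.0, 1.0, n) < p_sensitivity_ok,
                    "platform": platform,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[PIXEL_COLUMNS]
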