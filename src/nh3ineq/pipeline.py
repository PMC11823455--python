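"""End-to-end orchestration: filter -> oversample -> background ->
enhancement -> block-group aggregation -> inequality -> stratification ->
distance analyses.

Period-level runs compute their own percentile background; stratified runs
(calm/windy, cool/hot) reuse the all-days background of their parent period.
Everything is deterministic under the run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .enhancement import compute_background, compute_enhancement, select_background_decile
from .inequality import aggregate_blockgroups, inequality_table
from .oversampling import GridSpec, filter_pixels, oversample
from .spatial import (
    distance_profile,
    median_split,
    nearest_facility_distance,
    population_weighted_distance,
)
from .synthetic import SceneConfig, generate_meteorology, generate_scene, simulate_columns

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-scene analysis run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    period_label: str = "all"
    n_days: int = 120
    pixels_per_day: int = 150
    noise_cv: float = 0.15
    platform: str = "A"
    months: tuple | None = None  # e.g. (5, 6, 7) restricts to May-July
    max_cloud: float = 0.25
    response_exponent: float = 2.0
    background_percentile: float = 10.0
    stratify: bool = True
    select_decile: bool = False
    bin_width_km: float = 2.0  # block groups are ~5 km across; 1 km bins are mostly empty
    profile_max_km: float = 20.0
    noise_band_km: tuple = (15.0, 20.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scene = SceneConfig(**raw.pop("scene", {}))
        return cls(scene=scene, **raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload["scene"] = asdict(self.scene)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All stage outputs of one run, traceable to the config and seed."""

    period_label: str
    background_value: float
    background_percentile: float
    inequality: pd.DataFrame
    designed_inequality: dict
    strata: dict
    profile: object
    extent_km: float
    pw_distances_km: dict
    chosen_decile: int | None
    decile_report: pd.DataFrame | None
    n_pixels_simulated: int
    n_pixels_used: int
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "period_label": self.period_label,
            "background_value": self.background_value,
            "background_percentile": self.background_percentile,
            "inequality": self.inequality.to_dict(orient="records"),
            "designed_inequality": self.designed_inequality,
            "extent_km": self.extent_km,
            "pw_distances_km": self.pw_distances_km,
            "chosen_decile": self.chosen_decile,
            "n_pixels_simulated": self.n_pixels_simulated,
            "n_pixels_used": self.n_pixels_used,
            "provenance": self.provenance,
            "strata": {
                name: {
                    "inequality": s["inequality"].to_dict(orient="records"),
                    "extent_km": s["extent_km"],
                    "near_source_mean": s["near_source_mean"],
                    "n_pixels": s["n_pixels"],
                }
                for name, s in self.strata.items()
            },
        }
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _analyze_stratum(pixels, grid, k, background, blockgroups, demographics, groups,
                     reference, distances, bin_width_km, max_km, noise_band_km,
                     noise_2sigma=None):
    ogrid = oversample(pixels, grid, k=k)
    enh = compute_enhancement(ogrid, background)
    table = aggregate_blockgroups(enh, blockgroups)
    ineq = inequality_table(table, demographics, groups, reference)
    prof = distance_profile(
        table, distances, bin_width_km=bin_width_km, max_km=max_km,
        noise_band_km=noise_band_km, noise_2sigma=noise_2sigma,
    )
    return {
        "inequality": ineq,
        "profile": prof,
        "extent_km": prof.extent_km,
        "near_source_mean": float(prof.mean[0]),
        "n_pixels": len(pixels),
        "table": table,
    }


def run_all(config: RunConfig, output_dir=None) -> RunReport:
    """Execute the full pipeline on a freshly generated synthetic scene."""
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    scene = generate_scene(config.scene)
    met = generate_meteorology(config.n_days, seed=int(seeds[0]))
    pixels = simulate_columns(
        scene, met, config.pixels_per_day, config.noise_cv,
        seed=int(seeds[1]), platform=config.platform,
    )
    n_simulated = len(pixels)

    if config.months is not None:
        months = set(config.months)
        met = met.loc[met["date"].dt.month.isin(months)].reset_index(drop=True)
        pixels = pixels.loc[pixels["time"].dt.month.isin(months)].reset_index(drop=True)
    pixels = pixels.loc[pixels["platform"] == config.platform].reset_index(drop=True)
    pixels = filter_pixels(pixels, max_cloud=config.max_cloud)
    logger.info("%s: %d pixels after QC", config.period_label, len(pixels))

    grid = GridSpec.from_bounds(
        *config.scene.region_bounds, spacing_deg=config.scene.grid_spacing_deg
    )
    ogrid = oversample(pixels, grid, k=config.response_exponent)
    background = compute_background(
        ogrid, percentile=config.background_percentile, period_label=config.period_label
    )
    enh = compute_enhancement(ogrid, background)
    table = aggregate_blockgroups(enh, scene.blockgroups)
    groups = config.scene.demographic_groups
    reference = config.scene.reference_group
    ineq = inequality_table(table, scene.demographics, groups, reference)

    distances = nearest_facility_distance(scene.blockgroups.centroids, scene.facilities)
    profile = distance_profile(
        table, distances, bin_width_km=config.bin_width_km,
        max_km=config.profile_max_km, noise_band_km=config.noise_band_km,
    )
    pw_dist = {
        g: population_weighted_distance(distances, scene.demographics, g) for g in groups
    }

    strata = {}
    if config.stratify:
        dates = pixels["time"].dt.normalize()
        for variable in ("wind", "temp"):
            labels = median_split(met, variable)
            for stratum in labels["stratum"].unique():
                days = pd.to_datetime(labels.loc[labels["stratum"] == stratum, "date"])
                sub = pixels.loc[dates.isin(set(days))].reset_index(drop=True)
                # stratified runs reuse the all-days background and noise level
                strata[stratum] = _analyze_stratum(
                    sub, grid, config.response_exponent, background, scene.blockgroups,
                    scene.demographics, groups, reference, distances,
                    config.bin_width_km, config.profile_max_km, config.noise_band_km,
                    noise_2sigma=profile.noise_2sigma,
                )

    chosen, decile_report = (None, None)
    if config.select_decile:
        chosen, decile_report = select_background_decile(
            ogrid, scene.blockgroups, scene.demographics, groups, reference
        )

    report = RunReport(
        period_label=config.period_label,
        background_value=background.value,
        background_percentile=background.percentile,
        inequality=ineq,
        designed_inequality=scene.designed_inequality,
        strata=strata,
        profile=profile,
        extent_km=profile.extent_km,
        pw_distances_km=pw_dist,
        chosen_decile=chosen,
        decile_report=decile_report,
        n_pixels_simulated=n_simulated,
        n_pixels_used=len(pixels),
        provenance={"seed": config.seed, "config_digest": config.digest()},
    )
    if output_dir is not None:
        _persist(report, table, pixels, output_dir)
    return report


def _persist(report: RunReport, table, pixels, output_dir):
    import os

    os.makedirs(output_dir, exist_ok=True)
    report.to_json(os.path.join(output_dir, f"report_{report.period_label}.json"))
    table.to_csv(os.path.join(output_dir, f"blockgroups_{report.period_label}.csv"), index=False)
    report.inequality.to_csv(
        os.path.join(output_dir, f"inequality_{report.period_label}.csv"), index=False
    )
    report.profile.to_dataframe().to_csv(
        os.path.join(output_dir, f"profile_{report.period_label}.csv"), index=False
    )
    if report.decile_report is not None:
        report.decile_report.to_csv(
            os.path.join(output_dir, f"decile_selection_{report.period_label}.csv"), index=False
        )


def compare_platforms(reports_a: dict, reports_b: dict, z: float = 1.96) -> pd.DataFrame:
    """Compare inequalities from two platforms over coinciding periods.

    ``reports_a``/``reports_b`` map period label -> :class:`RunReport`.
    Returns per (period, group) the difference of absolute inequalities, the
    combined SEM, and an equivalence flag at the given z.
    """
    common = sorted(set(reports_a) & set(reports_b))
    if not common:
        raise ValueError("no overlapping period labels")
    rows = []
    for period in common:
        ia = reports_a[period].inequality.set_index("group")
        ib = reports_b[period].inequality.set_index("group")
        for g in ia.index.intersection(ib.index):
            diff = float(ia.loc[g, "absolute"] - ib.loc[g, "absolute"])
            sem = float(np.hypot(ia.loc[g, "sem_abs"], ib.loc[g, "sem_abs"]))
            rows.append(
                {
                    "period": period,
                    "group": g,
                    "abs_diff": diff,
                    "combined_sem": sem,
                    "equivalent": bool(abs(diff) <= z * sem),
                }
            )
    return pd.DataFrame(rows)


def passive_sampler_bias_example(
    peak_ppm: float = 1.7,
    peak_hours: float = 8.0,
    baseline_ppb: float = 10.0,
    window_days: float = 14.0,
    low_bias_fraction: float = 0.40,
) -> float:
    """Reported concentration (ppb) from a time-integrating passive sampler.

    A sampler integrating over ``window_days`` reports the time-weighted mean
    mixing ratio reduced by its documented low bias. The defaults illustrate
    how a multi-hour exceedance of the 1.7 ppm acute health standard can be
    reported as only ~30 ppb by a two-week sampler with a 40% low bias.
    """
    if window_days <= 0:
        raise ValueError("window must be positive")
    total_hours = 24.0 * window_days
    if not 0 <= peak_hours <= total_hours:
        raise ValueError("peak_hours must lie within the window")
    if not 0 <= low_bias_fraction < 1:
        raise ValueError("low_bias_fraction must lie in [0, 1)")
    peak_ppb = 1000.0 * peak_ppm
    mean_ppb = (peak_ppb * peak_hours + baseline_ppb * (total_hours - peak_hours)) / total_hours
    return mean_ppb * (1.0 - low_bias_fraction)
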