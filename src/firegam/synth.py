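"""Seeded synthetic data with the structure of the San Diego 2007 study season.

The generators emulate a 121-day late-summer/fall window (Aug 1 - Nov 29) for
one county split into six sub-regions: episodic, heavy-tailed wildfire-PM
bursts over a near-zero baseline; smooth seasonal weather with autocorrelated
noise and Santa Ana-like episodes (hot, dry) around the fire days; low,
weakly autocorrelated anthropogenic PM2.5; fixed demographic proportions; and
binomial daily ED-visit counts whose success probability follows the additive
logit model with a known "truth" parameter set, the exposure covariate being
the lag-kernel-weighted fire PM.

All randomness flows from one seed through named substreams, so covariates
and counts are jointly reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special

from .exposure import LagKernel, apply_lag_kernel, half_gaussian_kernel

__all__ = [
    "RegionConfig",
    "SyntheticConfig",
    "TruthParameters",
    "default_truth",
    "default_config",
    "default_populations",
    "generate_fire_pm",
    "generate_weather",
    "generate_anthropogenic_pm",
    "generate_demographics",
    "generate_ed_counts",
    "generate_station_network",
    "simulate_dataset",
    "aggregate_to_county",
]

_DECAY_RATE = 0.5          # 1/day, exponential decay of plume concentrations
_PEAK_JITTER_SD = 0.10     # lognormal sd of episode peak magnitudes
_BASELINE_MEDIAN_FRAC = 2.5e-4   # baseline median as a fraction of the peak


@dataclass(frozen=True)
class RegionConfig:
    """Marginal targets for one region (defaults follow the six sub-regions)."""

    region_id: str
    mean_visits: float
    fire_pm_mean: float
    fire_pm_max: float
    anthro_mean: float
    anthro_sd: float
    rh_mean: float
    rh_sd: float
    tmin_mean: float
    tmin_sd: float
    prop_age_lt24: float
    prop_income_gt50k: float
    lon: float = -117.1
    lat: float = 32.9
    population: int | None = None   # None -> calibrated from the truth


# Marginal targets for the six sub-regions (episodic-fire fall season).
_DEFAULT_REGIONS = (
    RegionConfig("SR1", 36.3, 15.56, 489.95, 0.66, 0.36, 35.38, 14.05, 50.99, 8.78, 0.37, 0.53, -116.70, 33.25),
    RegionConfig("SR2", 33.0, 12.99, 430.20, 0.86, 0.47, 42.27, 15.92, 52.56, 6.90, 0.32, 0.54, -117.25, 33.20),
    RegionConfig("SR3", 50.6,  8.16, 216.76, 1.13, 0.58, 43.68, 15.85, 56.75, 7.38, 0.40, 0.30, -117.15, 32.75),
    RegionConfig("SR4", 50.1, 15.19, 587.08, 0.94, 0.55, 42.37, 15.13, 56.85, 7.48, 0.41, 0.41, -117.05, 32.80),
    RegionConfig("SR5", 41.2,  7.28, 194.65, 0.81, 0.44, 39.49, 14.75, 55.70, 7.60, 0.36, 0.46, -116.95, 32.65),
    RegionConfig("SR6", 36.2, 14.67, 511.59, 0.69, 0.36, 35.44, 15.13, 54.18, 8.88, 0.36, 0.55, -116.60, 32.85),
)

# County-wide aggregate targets (used by single-region configs).
COUNTY_REGION = RegionConfig(
    "county", 247.4, 11.73, 403.47, 0.84, 0.44, 39.66, 14.87, 54.34, 7.75, 0.38, 0.47, -117.0, 32.9
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_days: int = 121
    start_date: str = "2007-08-01"
    regions: tuple[RegionConfig, ...] = _DEFAULT_REGIONS
    episode_days: tuple[int, ...] = (21, 82)   # mid-August and late-October bursts
    episode_magnitude: float | None = None     # ug/m3 peak of the main burst; None -> per-region max
    weather_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "episode_days", tuple(self.episode_days))
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for d in self.episode_days:
            if not (0 <= d < self.n_days):
                raise ValueError(f"episode day {d} outside [0, {self.n_days})")
        for r in self.regions:
            if r.population is not None and r.population <= 0:
                raise ValueError(f"region {r.region_id}: population must be > 0")
            for p in (r.prop_age_lt24, r.prop_income_gt50k):
                if not (0.0 < p < 1.0):
                    raise ValueError(f"region {r.region_id}: proportions must be in (0,1)")

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


@dataclass(frozen=True)
class TruthParameters:
    """Known generating parameters for the additive logit model.

    ``smooth_functions`` and ``interaction_surface`` are centered so they
    average to ~0 over the generating covariate distributions, keeping the
    intercept identifiable.
    """

    intercept: float
    linear_coefs: dict = field(default_factory=dict)       # per-unit log-odds
    indicator_coefs: dict = field(default_factory=dict)    # log-odds when true
    smooth_functions: dict = field(default_factory=dict)   # name -> callable
    interaction_surface: Callable | None = None            # (rh %, tmin F) -> log-odds
    kernel: LagKernel = field(default_factory=half_gaussian_kernel)


_REFERENCE_SEEDS = (1_000_001, 1_000_002, 1_000_003, 1_000_004, 1_000_005)
_reference_cache: dict = {}


def _reference_covariates():
    """Pooled covariate sample from the default generating mixture (fixed
    internal seeds), used to center the truth's nonlinear terms so they
    average to ~0 over the generating distribution."""
    if "sample" not in _reference_cache:
        frames = []
        for s in _REFERENCE_SEEDS:
            cfg = SyntheticConfig(seed=s)
            streams = _streams(cfg)
            a = generate_anthropogenic_pm(cfg, streams["anthro"])
            w = generate_weather(cfg, streams["weather"])
            frames.append(a.merge(w, on=["region_id", "date"]))
        _reference_cache["sample"] = pd.concat(frames, ignore_index=True)
    return _reference_cache["sample"]


def _anthro_smooth(amplitude: float = 0.15, knee: float = 1.2) -> Callable:
    """Saturating effect of anthropogenic PM2.5: linear rise, then plateau.

    Centered against the pooled generating distribution across regions.
    """
    ref = _reference_covariates()["anthro_pm25"].to_numpy()
    c0 = float(np.mean(np.minimum(ref, knee) / knee))

    def f(x):
        return amplitude * (np.minimum(np.asarray(x, dtype=float), knee) / knee - c0)

    return f


def _weather_surface(amplitude: float = 0.08) -> Callable:
    """Humidity/temperature interaction with an inverse-relationship ridge.

    Odds rise with humidity at moderate minimum temperature and fall off when
    both variables are high together; centered like the univariate smooth.
    """

    def raw(rh, tmin):
        zr = (np.asarray(rh, dtype=float) - 39.66) / 14.87
        zt = (np.asarray(tmin, dtype=float) - 54.34) / 7.75
        return zr * np.exp(-0.5 * zt**2)

    ref = _reference_covariates()
    c0 = float(np.mean(raw(ref["mean_rh"].to_numpy(), ref["min_temp"].to_numpy())))

    def g(rh, tmin):
        return amplitude * (raw(rh, tmin) - c0)

    return g


def default_truth() -> TruthParameters:
    """Truth on the scale of the sub-region model's reported coefficients."""
    return TruthParameters(
        intercept=-7.76,
        linear_coefs={
            "fire_pm": np.log(1.00093),               # per ug/m3 of lagged exposure
            "prop_income_gt50k": np.log(0.0087),      # per unit proportion
            "prop_age_lt24": np.log(5.584),
        },
        indicator_coefs={
            "is_monday": np.log(1.174),
            "is_tuesday": np.log(1.072),
            "is_sr3": np.log(0.512),
            "is_sr6": np.log(1.209),
        },
        smooth_functions={"anthro_pm25": _anthro_smooth()},
        interaction_surface=_weather_surface(),
    )


def _region_baseline_logodds(truth: TruthParameters, region: RegionConfig) -> float:
    eta = truth.intercept
    eta += truth.linear_coefs.get("prop_income_gt50k", 0.0) * region.prop_income_gt50k
    eta += truth.linear_coefs.get("prop_age_lt24", 0.0) * region.prop_age_lt24
    key = f"is_{region.region_id.lower()}"
    eta += truth.indicator_coefs.get(key, 0.0)
    return eta


def default_populations(truth: TruthParameters, regions=_DEFAULT_REGIONS) -> dict:
    """Binomial denominators calibrated so each region's expected daily count
    at baseline conditions matches its target mean.  With the default truth
    these come out at roughly 0.4-0.9 million per sub-region (about 3 million
    county-wide)."""
    out = {}
    for r in regions:
        p = special.expit(_region_baseline_logodds(truth, r))
        out[r.region_id] = int(round(r.mean_visits / p))
    return out


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **overrides)


def _streams(config: SyntheticConfig) -> dict:
    names = ["fire", "weather", "anthro", "counts", "stations"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {k: np.random.default_rng(s) for k, s in zip(names, children)}


# ---------------------------------------------------------------------------
# covariate generators


def generate_fire_pm(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-region daily fire-PM series (ug/m3), long format.

    Near-zero lognormal baseline plus episodic bursts: each episode day gets a
    lognormal peak that decays exponentially (rate 0.5/day).  The main (last)
    episode peaks at the configured magnitude; the secondary peak is sized so
    the series mean matches the region's target mean in expectation.
    """
    rng = rng if rng is not None else _streams(config)["fire"]
    decay_sum = 1.0 / (1.0 - np.exp(-_DECAY_RATE))
    frames = []
    for r in config.regions:
        peak_main = config.episode_magnitude if config.episode_magnitude is not None else r.fire_pm_max
        x = np.zeros(config.n_days)
        if peak_main > 0:
            # scale target mean in proportion when the magnitude is overridden
            target_mean = r.fire_pm_mean * peak_main / r.fire_pm_max
            base_median = _BASELINE_MEDIAN_FRAC * peak_main
            x = base_median * np.exp(rng.normal(0.0, 0.8, config.n_days))
            base_mean = base_median * np.exp(0.8**2 / 2)
            peaks = np.full(len(config.episode_days), peak_main, dtype=float)
            if len(peaks) > 1:
                secondary = max(
                    0.0,
                    ((target_mean - base_mean) * config.n_days / decay_sum - peak_main)
                    / (len(peaks) - 1),
                )
                peaks[:-1] = secondary
            jitter = np.exp(rng.normal(-0.5 * _PEAK_JITTER_SD**2, _PEAK_JITTER_SD, len(peaks)))
            for day, pk in zip(config.episode_days, peaks * jitter):
                k = np.arange(config.n_days - day)
                x[day:] += pk * np.exp(-_DECAY_RATE * k)
        frames.append(pd.DataFrame({"region_id": r.region_id, "date": config.dates(), "fire_pm10": x}))
    out = pd.concat(frames, ignore_index=True)
    # PM2.5 as a near-proportional subclass of PM10 (short transport distances)
    out["fire_pm25"] = 0.82 * out["fire_pm10"]
    return out


def _ar1(rng, n, phi, innovation_sd):
    e = rng.normal(0.0, innovation_sd, n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(max(1 - phi**2, 1e-12))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def generate_weather(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-region daily mean relative humidity (%) and minimum temperature (F).

    Seasonal sinusoid + shared county-scale AR(1) noise + small region noise;
    episode (Santa Ana-like) windows force dry, warm anomalies so humidity and
    temperature move oppositely around the fire days.  ``weather_noise_scale=0``
    yields the pure seasonal curves.
    """
    rng = rng if rng is not None else _streams(config)["weather"]
    t = np.arange(config.n_days, dtype=float)
    season = np.cos(2 * np.pi * t / 365.0)   # declining Aug -> Nov
    season = season - season.mean()          # centered so targets set the level
    shared_rh = _ar1(rng, config.n_days, 0.8, 1.0)
    shared_t = _ar1(rng, config.n_days, 0.7, 1.0)
    santa_ana = np.zeros(config.n_days)
    for day in config.episode_days:
        for k in range(3):
            if day + k < config.n_days:
                santa_ana[day + k] = max(santa_ana[day + k], np.exp(-0.7 * k))
    frames = []
    for r in config.regions:
        own_rh = _ar1(rng, config.n_days, 0.8, 1.0)
        own_t = _ar1(rng, config.n_days, 0.7, 1.0)
        ns = config.weather_noise_scale
        # AR(1) mixtures below have stationary sd 1.667 (phi=.8) / 1.400 (phi=.7)
        rh = (
            r.rh_mean
            - 0.90 * r.rh_sd * season
            + ns * (0.45 * r.rh_sd) * (0.85 * shared_rh + 0.53 * own_rh)
        )
        tm = (
            r.tmin_mean
            + 0.80 * r.tmin_sd * season
            + ns * (0.54 * r.tmin_sd) * (0.85 * shared_t + 0.53 * own_t)
        )
        rh = rh * (1.0 - 0.65 * santa_ana)   # dry anomaly during fire weather
        tm = tm + 4.0 * santa_ana            # warm anomaly
        frames.append(
            pd.DataFrame(
                {
                    "region_id": r.region_id,
                    "date": config.dates(),
                    "mean_rh": np.clip(rh, 0.0, 100.0),
                    "min_temp": np.clip(tm, 20.0, 110.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_anthropogenic_pm(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-region daily anthropogenic PM2.5 (ug/m3): lognormal AR(1), phi=0.7."""
    rng = rng if rng is not None else _streams(config)["anthro"]
    phi = 0.7
    frames = []
    for r in config.regions:
        if r.anthro_sd == 0:
            x = np.full(config.n_days, r.anthro_mean)
        else:
            s2 = np.log(1 + (r.anthro_sd / r.anthro_mean) ** 2)
            mu = np.log(r.anthro_mean) - s2 / 2
            z = _ar1(rng, config.n_days, phi, np.sqrt(s2 * (1 - phi**2)))
            x = np.clip(np.exp(mu + z), 0.05, 3.5)
        frames.append(pd.DataFrame({"region_id": r.region_id, "date": config.dates(), "anthro_pm25": x}))
    return pd.concat(frames, ignore_index=True)


def generate_demographics(config: SyntheticConfig) -> pd.DataFrame:
    """Fixed per-region proportions (no day-to-day variation)."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in config.regions],
            "prop_age_lt24": [r.prop_age_lt24 for r in config.regions],
            "prop_income_gt50k": [r.prop_income_gt50k for r in config.regions],
        }
    )


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """All daily covariates merged into the covariates.csv schema."""
    streams = _streams(config)
    fire = generate_fire_pm(config, streams["fire"])
    weather = generate_weather(config, streams["weather"])
    anthro = generate_anthropogenic_pm(config, streams["anthro"])
    cov = fire.merge(anthro, on=["region_id", "date"]).merge(weather, on=["region_id", "date"])
    return cov[["region_id", "date", "fire_pm25", "fire_pm10", "anthro_pm25", "mean_rh", "min_temp"]]


# ---------------------------------------------------------------------------
# response generator


def _weekday_indicators(dates: pd.Series) -> pd.DataFrame:
    wd = pd.DatetimeIndex(dates).dayofweek
    out = {}
    for i, name in enumerate(["monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"]):
        out[f"is_{name}"] = (wd == i).astype(float)
    return pd.DataFrame(out, index=dates.index if hasattr(dates, "index") else None)


def build_model_frame(
    covariates: pd.DataFrame,
    demographics: pd.DataFrame,
    populations: dict,
    kernel: LagKernel | None = None,
) -> pd.DataFrame:
    """Assemble the model-ready frame: lagged fire-PM exposure, weekday and
    region indicators, demographic proportions, and the trials column."""
    kernel = kernel if kernel is not None else half_gaussian_kernel()
    df = covariates.sort_values(["region_id", "date"]).reset_index(drop=True).copy()
    df["fire_pm"] = (
        df.groupby("region_id", sort=False)["fire_pm10"]
        .transform(lambda s: apply_lag_kernel(s.to_numpy(), kernel))
    )
    df = df.join(_weekday_indicators(df["date"]))
    regions = sorted(df["region_id"].unique())
    for r in regions:
        if len(regions) > 1:
            df[f"is_{r.lower()}"] = (df["region_id"] == r).astype(float)
    df = df.merge(demographics, on="region_id", how="left")
    missing = set(df["region_id"]) - set(populations)
    if missing:
        raise KeyError(f"no population for regions {sorted(missing)}")
    if any(populations[r] <= 0 for r in df["region_id"].unique()):
        raise ValueError("populations must be > 0")
    df["population"] = df["region_id"].map(populations).astype(float)
    return df


def generate_ed_counts(
    truth: TruthParameters,
    covariates: pd.DataFrame,
    demographics: pd.DataFrame,
    populations: dict,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Binomial daily visit counts from the additive logit truth.

    The linear predictor is assembled exactly from ``truth``: intercept,
    linear and indicator coefficients, centered smooth(s) of anthropogenic
    PM2.5, and the humidity/temperature interaction surface; the fire-PM term
    enters as the lag-kernel-weighted exposure.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = build_model_frame(covariates, demographics, populations, truth.kernel)
    eta = np.full(len(df), truth.intercept)
    for name, b in truth.linear_coefs.items():
        if name not in df.columns:
            raise KeyError(f"truth linear term {name!r} missing from covariates")
        eta = eta + b * df[name].to_numpy(dtype=float)
    for name, b in truth.indicator_coefs.items():
        if name in df.columns:
            eta = eta + b * df[name].to_numpy(dtype=float)
    for name, f in truth.smooth_functions.items():
        eta = eta + f(df[name].to_numpy(dtype=float))
    if truth.interaction_surface is not None:
        eta = eta + truth.interaction_surface(
            df["mean_rh"].to_numpy(dtype=float), df["min_temp"].to_numpy(dtype=float)
        )
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor from truth parameters")
    p = special.expit(eta)
    counts = rng.binomial(df["population"].to_numpy(dtype=int), p)
    return pd.DataFrame(
        {
            "region_id": df["region_id"],
            "date": df["date"],
            "visits": counts.astype(int),
            "population": df["population"].astype(int),
        }
    )


# ---------------------------------------------------------------------------
# station / zip fixtures for the interpolation-aggregation stage


def generate_station_network(
    config: SyntheticConfig,
    n_stations: int = 4,
    zips_per_region: int = 3,
    station_noise_sd: float = 1.5,
):
    """Synthetic weather-station network and zip-centroid table.

    Stations sample the same regional weather field as :func:`generate_weather`
    (each station reports its nearest region's series) plus independent
    station noise.  Every zip maps to exactly one region.  Returns
    ``(stations, station_weather, zips)`` data frames.
    """
    if n_stations < 1 or zips_per_region < 1:
        raise ValueError("need >= 1 station and >= 1 zip per region")
    streams = _streams(config)
    rng = streams["stations"]
    weather = generate_weather(config, streams["weather"])
    regions = list(config.regions)
    centers = np.array([[r.lon, r.lat] for r in regions])

    st_rows, wx_rows = [], []
    for s in range(n_stations):
        lon = centers[s % len(regions), 0] + rng.normal(0, 0.03)
        lat = centers[s % len(regions), 1] + rng.normal(0, 0.03)
        near = int(np.argmin((centers[:, 0] - lon) ** 2 + (centers[:, 1] - lat) ** 2))
        base = weather[weather["region_id"] == regions[near].region_id]
        st_rows.append({"station_id": f"ST{s+1}", "lon": lon, "lat": lat})
        wx_rows.append(
            pd.DataFrame(
                {
                    "station_id": f"ST{s+1}",
                    "lon": lon,
                    "lat": lat,
                    "date": base["date"].to_numpy(),
                    "mean_rh": np.clip(
                        base["mean_rh"].to_numpy() + rng.normal(0, station_noise_sd, config.n_days), 0, 100
                    ),
                    "min_temp": np.clip(
                        base["min_temp"].to_numpy() + rng.normal(0, station_noise_sd, config.n_days), 20, 110
                    ),
                }
            )
        )
    populations = default_populations(default_truth(), regions)
    zip_rows = []
    for r in regions:
        for k in range(zips_per_region):
            zip_rows.append(
                {
                    "zip": f"{r.region_id}Z{k+1}",
                    "lon": r.lon + rng.normal(0, 0.05),
                    "lat": r.lat + rng.normal(0, 0.05),
                    "population": max(1, int(populations[r.region_id] / zips_per_region)),
                    "region_id": r.region_id,
                }
            )
    zips = pd.DataFrame(zip_rows)
    if zips["zip"].duplicated().any():
        raise ValueError("duplicate zip identifiers")
    return pd.DataFrame(st_rows), pd.concat(wx_rows, ignore_index=True), zips


# ---------------------------------------------------------------------------
# end-to-end dataset assembly


def simulate_dataset(
    config: SyntheticConfig,
    truth: TruthParameters | None = None,
    populations: dict | None = None,
    with_stations: bool = False,
) -> dict:
    """Generate the full set of tables for one seeded run.

    Returns a dict with ``counts``, ``covariates``, ``demographics``,
    ``model_frame`` (lagged exposure + indicators, ready for fitting) and,
    optionally, the station/zip fixtures.
    """
    truth = truth if truth is not None else default_truth()
    streams = _streams(config)
    covariates = generate_covariates(config)
    demographics = generate_demographics(config)
    populations = populations if populations is not None else default_populations(truth, config.regions)
    counts = generate_ed_counts(truth, covariates, demographics, populations, streams["counts"])
    frame = build_model_frame(covariates, demographics, populations, truth.kernel)
    frame = frame.merge(counts[["region_id", "date", "visits"]], on=["region_id", "date"])
    frame["visits"] = frame["visits"].astype(float)
    out = {
        "counts": counts,
        "covariates": covariates,
        "demographics": demographics,
        "model_frame": frame,
        "populations": populations,
        "truth": truth,
    }
    if with_stations:
        stations, station_weather, zips = generate_station_network(config)
        out.update({"stations": stations, "station_weather": station_weather, "zips": zips})
    return out


def aggregate_to_county(dataset: dict, kernel: LagKernel | None = None) -> dict:
    """Population-weighted county aggregation of a multi-region dataset.

    Counts and populations sum; covariates aggregate by population weight.
    Returns a dataset dict with a single 'county' region (no demographic or
    region-indicator terms in its model frame).
    """
    kernel = kernel if kernel is not None else half_gaussian_kernel()
    cov = dataset["covariates"].copy()
    pops = dataset["populations"]
    cov["_w"] = cov["region_id"].map(pops).astype(float)
    value_cols = ["fire_pm25", "fire_pm10", "anthro_pm25", "mean_rh", "min_temp"]
    agg = (
        cov.groupby("date")
        .apply(
            lambda g: pd.Series({c: np.average(g[c], weights=g["_w"]) for c in value_cols}),
            include_groups=False,
        )
        .reset_index()
    )
    agg.insert(0, "region_id", "county")
    counts = (
        dataset["counts"].groupby("date", as_index=False)
        .agg(visits=("visits", "sum"), population=("population", "sum"))
    )
    counts.insert(0, "region_id", "county")
    demo = pd.DataFrame(
        {
            "region_id": ["county"],
            "prop_age_lt24": [np.average(dataset["demographics"]["prop_age_lt24"],
                                         weights=[pops[r] for r in dataset["demographics"]["region_id"]])],
            "prop_income_gt50k": [np.average(dataset["demographics"]["prop_income_gt50k"],
                                             weights=[pops[r] for r in dataset["demographics"]["region_id"]])],
        }
    )
    county_pop = {"county": int(counts["population"].iloc[0])}
    frame = build_model_frame(agg, demo, county_pop, kernel)
    frame = frame.merge(counts[["region_id", "date", "visits"]], on=["region_id", "date"])
    frame["visits"] = frame["visits"].astype(float)
    return {
        "counts": counts,
        "covariates": agg,
        "demographics": demo,
        "model_frame": frame,
        "populations": county_pop,
    }
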