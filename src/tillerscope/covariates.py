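"""Agroclimatic and soil covariate engineering.

Derives every model predictor from raw per-site-year inputs over the window
from planting to the field observation date: cumulative growing degree days
(GDD), the period-mean photothermal quotient (PTQ), period means of daily
minimum / maximum temperature and thermal amplitude, cumulative vapor
pressure deficit (VPD, a crop-stress proxy), cumulative moisture (rain plus
irrigation, extended one month pre-sowing to approximate soil water at
planting), soil nutrient areal masses (kg ha^-1 from concentration, bulk
density and sampling depth), and the clustering of realized plant densities
onto the three management targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import Constants, PD_TARGETS, STAGES

WEATHER_COLUMNS = ("date", "t_min", "t_max", "radiation", "vpd", "precip", "irrigation")


class MissingWeatherError(ValueError):
    """A required day is absent from the weather series."""


class DegeneratePeriodError(ValueError):
    """A covariate is undefined on the requested window."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeatherDay:
    """One day of site weather.

    Units: temperatures °C, radiation MJ m^-2 day^-1, vpd kPa, precipitation
    and irrigation mm.
    """

    date: date
    t_min: float
    t_max: float
    radiation: float
    vpd: float
    precip: float
    irrigation: float = 0.0

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError(f"{self.date}: t_min {self.t_min} > t_max {self.t_max}")
        for name in ("radiation", "vpd", "precip", "irrigation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.date}: {name} must be >= 0")


@dataclass(frozen=True)
class SoilProfile:
    """Per-site-year soil chemistry and physics.

    Concentrations are mg kg^-1 (NO3-N and NH4-N sampled 0-60 cm, Mehlich P
    0-15 cm); ``bulk_density`` is Mg m^-3; texture fractions are percent and
    must sum to 100 within 0.5. Areal nutrient masses (kg ha^-1) are derived
    on construction via :func:`nutrient_mass`.
    """

    ph: float
    om: float
    no3_conc: float
    nh4_conc: float
    p_conc: float
    cec: float
    sand: float
    silt: float
    clay: float
    bulk_density: float
    no3_kg: float = field(init=False)
    nh4_kg: float = field(init=False)
    p_kg: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("om", "no3_conc", "nh4_conc", "p_conc", "cec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.sand + self.silt + self.clay - 100.0) > 0.5:
            raise ValueError(
                f"sand+silt+clay must sum to 100 +/- 0.5, got "
                f"{self.sand + self.silt + self.clay:.2f}"
            )
        consts = Constants()
        object.__setattr__(
            self, "no3_kg", nutrient_mass(self.no3_conc, self.bulk_density, consts.n_depth_cm)
        )
        object.__setattr__(
            self, "nh4_kg", nutrient_mass(self.nh4_conc, self.bulk_density, consts.n_depth_cm)
        )
        object.__setattr__(
            self, "p_kg", nutrient_mass(self.p_conc, self.bulk_density, consts.p_depth_cm)
        )


@dataclass(frozen=True)
class ObservationRecord:
    """One field measurement of tiller density with its management context."""

    site_year: str
    genotype: str
    sow_date: date
    obs_date: date
    stage: str
    target_pd: int
    observed_pd: float
    tiller_density: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.obs_date <= self.sow_date:
            raise ValueError(
                f"{self.site_year}: obs_date {self.obs_date} must follow sow_date "
                f"{self.sow_date}"
            )
        if not 0 <= self.tiller_density <= Constants().y_max:
            raise ValueError(
                f"{self.site_year}: tiller_density {self.tiller_density} outside "
                f"[0, {Constants().y_max}]"
            )
        if self.observed_pd <= 0:
            raise ValueError("observed_pd must be positive")


@dataclass(frozen=True)
class CovariateVector:
    """The derived predictor set for one observation."""

    gdd: float
    ptq: float
    t_min_mean: float
    t_max_mean: float
    t_amp_mean: float
    cm: float
    vpd_cum: float
    pd_class: str
    genotype: str
    ph: float
    om: float
    no3_kg: float
    nh4_kg: float
    p_kg: float
    cec: float
    sand: float
    silt: float
    clay: float

    def __post_init__(self) -> None:
        if min(self.gdd, self.vpd_cum, self.cm) < 0:
            raise ValueError("cumulative covariates must be >= 0")
        if self.t_min_mean > self.t_max_mean:
            raise ValueError("t_min_mean must not exceed t_max_mean")


# ---------------------------------------------------------------------------
# weather-series helpers
# ---------------------------------------------------------------------------


def as_weather_frame(series) -> pd.DataFrame:
    """Coerce a list of :class:`WeatherDay` or a DataFrame to a tidy frame."""
    if isinstance(series, pd.DataFrame):
        missing = [c for c in WEATHER_COLUMNS if c not in series.columns and c != "irrigation"]
        if missing:
            raise ValueError(f"weather frame missing columns: {missing}")
        out = series.copy()
        if "irrigation" not in out.columns:
            out["irrigation"] = 0.0
    else:
        out = pd.DataFrame([vars(d) if not isinstance(d, dict) else d for d in series])
    out["date"] = pd.to_datetime(out["date"]).dt.date
    return out.sort_values("date").reset_index(drop=True)


def _window_frame(series, start: date, end: date) -> pd.DataFrame:
    """Rows of the series within the closed window [start, end].

    Raises :class:`MissingWeatherError` naming the first absent day.
    """
    frame = as_weather_frame(series)
    if end < start:
        raise ValueError(f"window end {end} precedes start {start}")
    sub = frame[(frame["date"] >= start) & (frame["date"] <= end)]
    have = set(sub["date"])
    n_days = (end - start).days + 1
    for k in range(n_days):
        day = start + timedelta(days=k)
        if day not in have:
            raise MissingWeatherError(f"weather series is missing {day.isoformat()}")
    return sub


def _daily_mean_temp(t_min, t_max) -> np.ndarray:
    return (np.asarray(t_min, float) + np.asarray(t_max, float)) / 2.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def daily_gdd(day: WeatherDay, consts: Constants = Constants()) -> float:
    """Growing degree days for one day: mean temperature above the 10 °C
    base, with the daily value capped at 30 °C.

    With ``gdd_cap_on == "mean"`` (default) the cap applies to the daily mean
    temperature; with ``"tmax"`` it applies to the daily maximum before
    averaging.
    """
    if consts.gdd_cap_on == "tmax":
        t_mean = (day.t_min + min(day.t_max, consts.t_cap)) / 2.0
        return max(0.0, t_mean - consts.t_base)
    t_mean = (day.t_min + day.t_max) / 2.0
    return max(0.0, min(t_mean, consts.t_cap) - consts.t_base)


def cumulative_gdd(series, sow_date: date, obs_date: date,
                   consts: Constants = Constants()) -> float:
    """Sum of daily GDD over the closed window [sow_date, obs_date].

    The degenerate window (obs_date == sow_date) accumulates nothing.
    """
    if obs_date == sow_date:
        return 0.0
    win = _window_frame(series, sow_date, obs_date)
    if consts.gdd_cap_on == "tmax":
        t_mean = (win["t_min"].to_numpy() + np.minimum(win["t_max"].to_numpy(), consts.t_cap)) / 2.0
        daily = np.maximum(0.0, t_mean - consts.t_base)
    else:
        t_mean = _daily_mean_temp(win["t_min"], win["t_max"])
        daily = np.maximum(0.0, np.minimum(t_mean, consts.t_cap) - consts.t_base)
    return float(daily.sum())


def photothermal_quotient(series, sow_date: date, obs_date: date,
                          consts: Constants = Constants()) -> float:
    """Period-mean daily solar radiation divided by (period-mean temperature
    minus the 10 °C base), MJ m^-2 °C^-1 day^-1.

    The denominator uses the uncapped period-mean temperature; a period mean
    at or below the base temperature is a :class:`DegeneratePeriodError`.
    """
    if obs_date <= sow_date:
        raise DegeneratePeriodError("photothermal quotient needs a non-empty period")
    win = _window_frame(series, sow_date, obs_date)
    mean_temp = float(_daily_mean_temp(win["t_min"], win["t_max"]).mean())
    denom = mean_temp - consts.t_base
    if denom <= 0:
        raise DegeneratePeriodError(
            f"period mean temperature {mean_temp:.2f} °C does not exceed the "
            f"base temperature {consts.t_base} °C"
        )
    return float(win["radiation"].mean()) / denom


def cumulative_vpd(series, sow_date: date, obs_date: date) -> float:
    """Vapor pressure deficit (kPa) summed over [sow_date, obs_date]."""
    if obs_date == sow_date:
        return 0.0
    win = _window_frame(series, sow_date, obs_date)
    return float(win["vpd"].sum())


def cumulative_moisture(series, sow_date: date, obs_date: date,
                        consts: Constants = Constants()) -> float:
    """Precipitation plus irrigation (mm) summed from one month pre-sowing
    to the observation date."""
    start = sow_date - timedelta(days=consts.pre_sow_days)
    win = _window_frame(series, start, obs_date)
    return float((win["precip"] + win["irrigation"]).sum())


def temp_means(series, sow_date: date, obs_date: date) -> tuple[float, float, float]:
    """Period means of daily minimum and maximum temperature and of the
    daily thermal amplitude (t_max - t_min), over [sow_date, obs_date]."""
    if obs_date <= sow_date:
        raise DegeneratePeriodError("temperature means need a non-empty period")
    win = _window_frame(series, sow_date, obs_date)
    t_min_mean = float(win["t_min"].mean())
    t_max_mean = float(win["t_max"].mean())
    t_amp_mean = float((win["t_max"] - win["t_min"]).mean())
    return t_min_mean, t_max_mean, t_amp_mean


def nutrient_mass(conc_mg_kg: float, bulk_density: float, depth_cm: float) -> float:
    """Convert a soil-test concentration (mg kg^-1) to an areal mass
    (kg ha^-1) through the sampled soil mass.

    Soil mass per hectare over the sampling depth is
    ``bulk_density (Mg m^-3) x depth (m) x 10^7 kg ha^-1``; multiplying by the
    concentration (10^-6 kg nutrient per kg soil) gives
    ``conc x bulk_density x depth_m x 10`` kg ha^-1.
    """
    if conc_mg_kg < 0:
        raise ValueError("concentration must be >= 0")
    if bulk_density <= 0 or depth_cm <= 0:
        raise ValueError("bulk density and depth must be positive")
    return conc_mg_kg * bulk_density * (depth_cm / 100.0) * 10.0


def classify_plant_density(observed_pd: float) -> str:
    """Cluster a realized plant density onto the nearest management target.

    Targets 25000 / 42000 / 60000 plants ha^-1 map to classes A / B / C;
    an equidistant density is assigned the lower target.
    """
    if observed_pd <= 0:
        raise ValueError("observed_pd must be positive")
    best = min(PD_TARGETS.items(), key=lambda kv: (abs(observed_pd - kv[1]), kv[1]))
    return best[0]


def build_covariates(obs: ObservationRecord, weather, soil: SoilProfile,
                     consts: Constants = Constants()) -> CovariateVector:
    """Assemble the full predictor vector for one observation.

    Weather must cover [sow_date - pre_sow_days, obs_date]; component errors
    are re-raised with the observation identifier attached.
    """
    try:
        t_min_mean, t_max_mean, t_amp_mean = temp_means(weather, obs.sow_date, obs.obs_date)
        return CovariateVector(
            gdd=cumulative_gdd(weather, obs.sow_date, obs.obs_date, consts),
            ptq=photothermal_quotient(weather, obs.sow_date, obs.obs_date, consts),
            t_min_mean=t_min_mean,
            t_max_mean=t_max_mean,
            t_amp_mean=t_amp_mean,
            cm=cumulative_moisture(weather, obs.sow_date, obs.obs_date, consts),
            vpd_cum=cumulative_vpd(weather, obs.sow_date, obs.obs_date),
            pd_class=classify_plant_density(obs.observed_pd),
            genotype=obs.genotype,
            ph=soil.ph, om=soil.om,
            no3_kg=soil.no3_kg, nh4_kg=soil.nh4_kg, p_kg=soil.p_kg,
            cec=soil.cec, sand=soil.sand, silt=soil.silt, clay=soil.clay,
        )
    except ValueError as err:
        raise type(err)(
            f"{obs.site_year} {obs.stage} ({obs.obs_date}): {err}"
        ) from err


# ---------------------------------------------------------------------------
# table-level assembly (CSV schemas of the pipeline)
# ---------------------------------------------------------------------------

#: Columns of the assembled model frame that are predictors.
PREDICTOR_COLUMNS = (
    "gdd", "ptq", "t_min_mean", "t_max_mean", "t_amp_mean", "cm", "vpd_cum",
    "observed_pd", "pd_class", "genotype",
    "ph", "om", "no3_kg", "nh4_kg", "p_kg", "cec", "sand", "silt", "clay",
)


def soil_from_row(row) -> SoilProfile:
    return SoilProfile(
        ph=float(row["ph"]), om=float(row["om"]),
        no3_conc=float(row["no3_conc"]), nh4_conc=float(row["nh4_conc"]),
        p_conc=float(row["p_conc"]), cec=float(row["cec"]),
        sand=float(row["sand"]), silt=float(row["silt"]), clay=float(row["clay"]),
        bulk_density=float(row["bulk_density"]),
    )


def build_covariate_table(observations: pd.DataFrame, weather: pd.DataFrame,
                          soil: pd.DataFrame,
                          consts: Constants = Constants()) -> pd.DataFrame:
    """Build the model frame: one row per observation with all predictors.

    ``observations`` needs columns site_year, genotype, sow_date, obs_date,
    stage, target_pd, observed_pd, tiller_density (and optionally season);
    ``weather`` one row per site-year x date; ``soil`` one row per site-year.
    """
    for col in ("site_year", "genotype", "sow_date", "obs_date", "stage",
                "target_pd", "observed_pd", "tiller_density"):
        if col not in observations.columns:
            raise ValueError(f"observations table is missing column {col!r}")
    if "site_year" not in weather.columns:
        raise ValueError("weather table is missing column 'site_year'")
    if "site_year" not in soil.columns:
        raise ValueError("soil table is missing column 'site_year'")

    weather_by_site = {sy: as_weather_frame(grp) for sy, grp in weather.groupby("site_year")}
    soil_by_site = {row["site_year"]: soil_from_row(row) for _, row in soil.iterrows()}

    # plots sharing a site-year and date share every climate covariate
    climate_cache: dict[tuple, CovariateVector] = {}
    rows = []
    for _, rec in observations.iterrows():
        sy = rec["site_year"]
        if sy not in weather_by_site:
            raise ValueError(f"no weather series for site-year {sy!r}")
        if sy not in soil_by_site:
            raise ValueError(f"no soil profile for site-year {sy!r}")
        obs = ObservationRecord(
            site_year=sy, genotype=str(rec["genotype"]),
            sow_date=pd.Timestamp(rec["sow_date"]).date(),
            obs_date=pd.Timestamp(rec["obs_date"]).date(),
            stage=str(rec["stage"]), target_pd=int(rec["target_pd"]),
            observed_pd=float(rec["observed_pd"]),
            tiller_density=float(rec["tiller_density"]),
        )
        key = (sy, obs.sow_date, obs.obs_date)
        if key in climate_cache:
            base = climate_cache[key]
            vec = CovariateVector(
                gdd=base.gdd, ptq=base.ptq, t_min_mean=base.t_min_mean,
                t_max_mean=base.t_max_mean, t_amp_mean=base.t_amp_mean,
                cm=base.cm, vpd_cum=base.vpd_cum,
                pd_class=classify_plant_density(obs.observed_pd),
                genotype=obs.genotype,
                ph=base.ph, om=base.om, no3_kg=base.no3_kg,
                nh4_kg=base.nh4_kg, p_kg=base.p_kg, cec=base.cec,
                sand=base.sand, silt=base.silt, clay=base.clay,
            )
        else:
            vec = build_covariates(obs, weather_by_site[sy], soil_by_site[sy], consts)
            climate_cache[key] = vec
        season = rec["season"] if "season" in observations.columns else obs.sow_date.year
        rows.append({
            "site_year": sy, "season": int(season), "genotype": obs.genotype,
            "stage": obs.stage, "target_pd": obs.target_pd,
            "observed_pd": obs.observed_pd, "tiller_density": obs.tiller_density,
            "gdd": vec.gdd, "ptq": vec.ptq,
            "t_min_mean": vec.t_min_mean, "t_max_mean": vec.t_max_mean,
            "t_amp_mean": vec.t_amp_mean, "cm": vec.cm, "vpd_cum": vec.vpd_cum,
            "pd_class": vec.pd_class,
            "ph": vec.ph, "om": vec.om, "no3_kg": vec.no3_kg,
            "nh4_kg": vec.nh4_kg, "p_kg": vec.p_kg, "cec": vec.cec,
            "sand": vec.sand, "silt": vec.silt, "clay": vec.clay,
        })
    return pd.DataFrame(rows)
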