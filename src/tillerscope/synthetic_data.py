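"""Synthetic multi-season, multi-site trial generator with known truth.

Emulates the statistical structure of a Central High Plains corn tillering
trial: 3 seasons x 6 sites (17-18 site-years), split-plot management with
three plant-density targets and two genotypes, five observation stages, daily
weather driven by a seasonal sinusoid, and per-site-year soil chemistry drawn
from the envelopes of the real study region. Tiller densities are drawn from
a configurable ground-truth response on the logit scale, so every pipeline
stage (fitting, ranking, attribution, threshold extraction) can be tested
against known answers.

Weather is generated independently per site-year (no spatial correlation)
and the truth is additive on the logit scale — deliberate simplifications
sufficient for parameter-recovery testing, not a crop-growth simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import Constants, PD_TARGETS
from .covariates import build_covariate_table

STAGE_OFFSETS_DEFAULT = {"V5": 30, "V10": 50, "V16": 65, "R3": 85, "R6": 120}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator settings; defaults emulate the real trial network.

    Soil envelopes are the observed site ranges of the study region
    (pH 5.2-7.9, OM 1.0-6.2 %, NO3 1.8-43.5 mg kg^-1, P 13.3-118 mg kg^-1);
    weather sinusoid parameters give Kansas-like May-September series; stage
    offsets are days after sowing.
    """

    n_seasons: int = 3
    n_sites_per_season: int = 6
    first_season: int = 2019
    pd_targets: tuple[int, ...] = (25000, 42000, 60000)
    pd_noise_sd: float = 2500.0
    genotypes: tuple[str, ...] = ("P08", "P06")
    n_reps: int = 2
    stage_offsets: dict = field(default_factory=lambda: dict(STAGE_OFFSETS_DEFAULT))
    # weather model
    tmax_base: float = 19.5          # °C, site-mean level of the sinusoid
    tmax_site_sd: float = 1.5
    tmax_season_amp: float = 13.5    # °C, seasonal amplitude (peak mid-July)
    tmax_daily_sd: float = 2.5
    amp_mean: float = 13.0           # °C, mean daily thermal amplitude
    amp_sd: float = 1.5
    rad_base: float = 18.0           # MJ m^-2 day^-1
    rad_season_amp: float = 7.0
    rad_daily_sd: float = 3.0
    vpd_intercept: float = 0.9       # kPa day^-1 at t_max = 22 °C
    vpd_slope: float = 0.07          # kPa per °C of t_max above 22
    vpd_daily_sd: float = 0.25
    precip_prob: float = 0.25
    precip_scale: float = 8.0        # mm, exponential wet-day amount
    irrigated_fraction: float = 0.5
    irrigation_weekly_mm: float = 25.0
    # soil envelopes (uniform sampling ranges)
    ph_range: tuple[float, float] = (5.2, 7.9)
    om_range: tuple[float, float] = (1.0, 6.2)
    no3_range: tuple[float, float] = (1.8, 43.5)
    nh4_range: tuple[float, float] = (0.0, 36.4)
    p_range: tuple[float, float] = (13.3, 118.0)
    cec_range: tuple[float, float] = (5.9, 25.6)
    bulk_density_range: tuple[float, float] = (1.1, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pd_noise_sd < 0:
            raise ValueError("pd_noise_sd must be >= 0")
        if any(t <= 0 for t in self.pd_targets):
            raise ValueError("plant-density targets must be positive")

    def seasons(self) -> list[int]:
        return [self.first_season + i for i in range(self.n_seasons)]


@dataclass(frozen=True)
class Effect:
    """One additive logit-scale effect: a logistic ramp in a covariate.

    Contribution is ``direction * amp * (2 * sigmoid((x - loc)/scale) - 1)``,
    antisymmetric about ``loc`` (zero there, +/- amp at the extremes);
    ``direction`` +1 makes high covariate values favorable (rising), -1
    unfavorable (falling). ``classes`` / ``seasons`` restrict where the
    effect is active (None = everywhere), the latter enabling truths whose
    structure shifts between seasons.
    """

    covariate: str                  # model-frame column, e.g. "gdd"
    amp: float
    loc: float
    scale: float
    direction: int = 1
    classes: tuple[str, ...] | None = None
    seasons: tuple[int, ...] | None = None

    def contribution(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.covariate].to_numpy(float)
        val = self.direction * self.amp * (
            2.0 / (1.0 + np.exp(-(x - self.loc) / self.scale)) - 1.0)
        if self.classes is not None:
            val = val * frame["pd_class"].isin(self.classes).to_numpy(float)
        if self.seasons is not None:
            val = val * frame["season"].isin(self.seasons).to_numpy(float)
        return val


@dataclass(frozen=True)
class TrueResponse:
    """Ground-truth response: per-class intercepts plus additive logit
    effects, and the observation-noise model.

    ``noise`` is ``"beta_binomial"`` (probability jittered with a Beta of
    dispersion ``rho``, then a binomial draw — realistic overdispersion),
    ``"gaussian"`` (additive density-scale noise of SD ``gauss_sd``), or
    ``"none"``.
    """

    intercepts: dict = field(default_factory=lambda: {"A": -2.2, "B": -2.2, "C": -2.2})
    effects: tuple[Effect, ...] = ()
    noise: str = "beta_binomial"
    rho: float = 0.02
    gauss_sd: float = 8000.0

    def __post_init__(self) -> None:
        if self.noise not in ("beta_binomial", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not all(np.isfinite(v) for v in self.intercepts.values()):
            raise ValueError("intercepts imply probabilities outside (0, 1)")
        if self.noise == "beta_binomial" and not 0 < self.rho < 1:
            raise ValueError("beta-binomial dispersion rho must lie in (0, 1)")

    def eta(self, frame: pd.DataFrame) -> np.ndarray:
        out = frame["pd_class"].map(self.intercepts).to_numpy(float)
        if np.any(np.isnan(out)):
            raise ValueError("intercepts missing for some pd_class level")
        for eff in self.effects:
            out = out + eff.contribution(frame)
        return out

    def prob(self, frame: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.eta(frame)))

    def manifest(self) -> dict:
        return {
            "intercepts": dict(self.intercepts),
            "effects": [asdict(e) for e in self.effects],
            "noise": self.noise, "rho": self.rho, "gauss_sd": self.gauss_sd,
            "true_thresholds": {e.covariate: e.loc for e in self.effects},
        }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _site_weather(rng: np.random.Generator, cfg: GeneratorConfig,
                  site_year: str, sow: date, last: date, irrigated: bool) -> pd.DataFrame:
    start = sow - timedelta(days=Constants().pre_sow_days)
    days = pd.date_range(start, last, freq="D")
    doy = days.dayofyear.to_numpy(float)
    site_level = cfg.tmax_base + rng.normal(0, cfg.tmax_site_sd)
    t_max = (site_level + cfg.tmax_season_amp * np.cos(2 * np.pi * (doy - 196) / 365.0)
             + rng.normal(0, cfg.tmax_daily_sd, len(days)))
    amp = np.clip(rng.normal(cfg.amp_mean, cfg.amp_sd, len(days)), 3.0, None)
    t_min = t_max - amp
    rad = np.clip(cfg.rad_base + cfg.rad_season_amp * np.cos(2 * np.pi * (doy - 172) / 365.0)
                  + rng.normal(0, cfg.rad_daily_sd, len(days)), 1.0, None)
    vpd = np.clip(cfg.vpd_intercept + cfg.vpd_slope * (t_max - 22.0)
                  + rng.normal(0, cfg.vpd_daily_sd, len(days)), 0.05, None)
    wet = rng.random(len(days)) < cfg.precip_prob
    precip = np.where(wet, rng.exponential(cfg.precip_scale, len(days)), 0.0)
    irrigation = np.zeros(len(days))
    if irrigated:
        after_sow = days.date >= sow
        weekly = (days.date - sow) // timedelta(days=1) % 7 == 0
        irrigation[after_sow & weekly] = cfg.irrigation_weekly_mm
    return pd.DataFrame({
        "site_year": site_year, "date": days.date, "t_min": t_min,
        "t_max": t_max, "radiation": rad, "vpd": vpd, "precip": precip,
        "irrigation": irrigation,
    })


def _site_soil(rng: np.random.Generator, cfg: GeneratorConfig, site_year: str) -> dict:
    sand = rng.uniform(15.0, 65.0)
    clay = rng.uniform(10.0, 30.0)
    return {
        "site_year": site_year,
        "ph": rng.uniform(*cfg.ph_range), "om": rng.uniform(*cfg.om_range),
        "no3_conc": rng.uniform(*cfg.no3_range),
        "nh4_conc": rng.uniform(*cfg.nh4_range),
        "p_conc": rng.uniform(*cfg.p_range), "cec": rng.uniform(*cfg.cec_range),
        "sand": sand, "clay": clay, "silt": 100.0 - sand - clay,
        "bulk_density": rng.uniform(*cfg.bulk_density_range),
    }


def generate(config: GeneratorConfig, truth: TrueResponse,
             seed: int | None = None,
             consts: Constants = Constants()) -> dict:
    """Generate one synthetic dataset.

    Returns a dict with keys ``weather``, ``soil``, ``observations`` (the
    three CSV-schema DataFrames the covariates module reads), ``frame`` (the
    assembled model frame with true probabilities attached) and ``manifest``
    (the truth record, for recovery tests). Fully reproducible from the seed
    (``seed`` argument overrides ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = {t: c for c, t in PD_TARGETS.items()}
    max_offset = max(config.stage_offsets.values())

    weather_parts, soil_rows, obs_rows = [], [], []
    for season in config.seasons():
        for i in range(config.n_sites_per_season):
            site_year = f"Site{i + 1:02d} {season}"
            sow = date(season, 4, 28) + timedelta(days=int(rng.integers(0, 15)))
            last = sow + timedelta(days=max_offset + 1)
            irrigated = rng.random() < config.irrigated_fraction
            weather_parts.append(
                _site_weather(rng, config, site_year, sow, last, irrigated))
            soil_rows.append(_site_soil(rng, config, site_year))
            for target in config.pd_targets:
                for gt in config.genotypes:
                    for _ in range(config.n_reps):
                        observed_pd = max(
                            5000.0, target + rng.normal(0, config.pd_noise_sd))
                        for stage, off in config.stage_offsets.items():
                            obs_rows.append({
                                "site_year": site_year, "season": season,
                                "genotype": gt, "sow_date": sow,
                                "obs_date": sow + timedelta(days=int(off)),
                                "stage": stage, "target_pd": target,
                                "observed_pd": observed_pd,
                                "tiller_density": 0.0,
                            })

    weather = pd.concat(weather_parts, ignore_index=True)
    soil = pd.DataFrame(soil_rows)
    observations = pd.DataFrame(obs_rows)

    frame = build_covariate_table(observations, weather, soil, consts)
    p_true = truth.prob(frame)
    if np.any(p_true <= 0) or np.any(p_true >= 1):
        raise ValueError("truth implies probabilities outside (0, 1)")

    if truth.noise == "none":
        density = p_true * consts.y_max
    elif truth.noise == "gaussian":
        density = p_true * consts.y_max + rng.normal(0, truth.gauss_sd, len(p_true))
    else:
        a = p_true * (1 - truth.rho) / truth.rho
        b = (1 - p_true) * (1 - truth.rho) / truth.rho
        p_obs = rng.beta(a, b)
        density = rng.binomial(consts.y_max, p_obs).astype(float)
    density = np.clip(density, 0.0, float(consts.y_max))

    observations["tiller_density"] = density
    frame["tiller_density"] = density
    frame["true_probability"] = p_true

    manifest = {
        "generator": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(config).items()},
        "truth": truth.manifest(),
        "seed": int(config.seed if seed is None else seed),
        "n_observations": int(len(observations)),
    }
    return {"weather": weather, "soil": soil, "observations": observations,
            "frame": frame, "manifest": manifest}


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def scenario_presets() -> dict[str, tuple[GeneratorConfig, TrueResponse]]:
    """Named generator/truth pairs for the recurring test scenarios.

    - ``null``: constant probability 0.1, no covariate effects — exercises
      null-signal recovery.
    - ``gdd_step``: a single sharp thermal-time threshold at 200 °C day with
      a compressed observation schedule placing dense support around it —
      exercises function and threshold recovery.
    - ``exm``: density-class-dependent VPD / T_max ceilings plus thermal and
      fertility effects, calibrated so the density ceiling stays near the
      150000 tillers ha^-1 scale observed in the field — exercises candidate
      ranking.
    - ``season_shift``: a soil-nitrate effect active in the first two
      seasons only — exercises the attribution procedure when the held-out
      season is structurally different.
    """
    base = GeneratorConfig()

    null_truth = TrueResponse(
        intercepts={"A": np.log(0.1 / 0.9), "B": np.log(0.1 / 0.9),
                    "C": np.log(0.1 / 0.9)},
        effects=(), noise="beta_binomial", rho=0.02,
    )

    gdd_cfg = GeneratorConfig(
        stage_offsets={"V5": 15, "V10": 30, "V16": 45, "R3": 60, "R6": 80},
        tmax_base=17.5,
    )
    gdd_truth = TrueResponse(
        intercepts={"A": 0.0, "B": 0.0, "C": 0.0},
        effects=(Effect("gdd", amp=1.2, loc=200.0, scale=30.0),),
        noise="beta_binomial", rho=0.02,
    )

    exm_truth = TrueResponse(
        intercepts={"A": -4.2, "B": -4.6, "C": -5.0},
        effects=(
            Effect("gdd", amp=1.0, loc=450.0, scale=80.0),
            Effect("ptq", amp=0.4, loc=1.0, scale=0.15),
            Effect("vpd_cum", amp=0.5, loc=30.0, scale=10.0),
            Effect("vpd_cum", amp=0.6, loc=200.0, scale=25.0,
                   direction=-1, classes=("B",)),
            Effect("vpd_cum", amp=0.8, loc=150.0, scale=25.0,
                   direction=-1, classes=("C",)),
            Effect("t_max_mean", amp=0.4, loc=22.0, scale=1.5,
                   classes=("A", "B")),
            Effect("t_max_mean", amp=0.4, loc=26.0, scale=1.5, classes=("C",)),
            Effect("no3_kg", amp=0.3, loc=200.0, scale=40.0,
                   direction=-1, classes=("A", "C")),
            Effect("p_kg", amp=0.3, loc=100.0, scale=25.0, classes=("A",)),
            Effect("p_kg", amp=0.3, loc=150.0, scale=30.0,
                   direction=-1, classes=("C",)),
        ),
        noise="beta_binomial", rho=0.02,
    )

    # attribution needs enough distinct soil profiles per season for the
    # season-inconsistent effect to be identifiable against the smooths of
    # correlated covariates
    shift_cfg = GeneratorConfig(n_sites_per_season=10)
    shift_truth = TrueResponse(
        intercepts={"A": -1.8, "B": -2.2, "C": -2.6},
        effects=(
            Effect("gdd", amp=1.0, loc=450.0, scale=80.0),
            Effect("no3_kg", amp=1.5, loc=150.0, scale=50.0,
                   direction=-1, seasons=(2019, 2020)),
        ),
        noise="beta_binomial", rho=0.02,
    )

    return {
        "null": (base, null_truth),
        "gdd_step": (gdd_cfg, gdd_truth),
        "exm": (base, exm_truth),
        "season_shift": (shift_cfg, shift_truth),
    }
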