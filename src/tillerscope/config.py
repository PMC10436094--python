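"""Pipeline-wide configuration constants.

All fixed quantities of the analysis live here so that a single YAML file can
override them: the thermal-time parameters, the assumed field-scale maximum
tiller density, the pre-sowing moisture window, the probability level that
defines non-limiting thresholds, and the soil sampling depths used to convert
nutrient concentrations to areal masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: Plant-density targets (plants ha^-1) and their cluster labels.
PD_TARGETS: dict[str, int] = {"A": 25000, "B": 42000, "C": 60000}

#: Development stages in phenological order.
STAGES: tuple[str, ...] = ("V5", "V10", "V16", "R3", "R6")


@dataclass(frozen=True)
class Constants:
    """Fixed analysis configuration with field-study defaults.

    Attributes
    ----------
    t_base:
        Crop base temperature (°C) for growing degree days and the
        photothermal quotient.
    t_cap:
        Forced daily maximum (°C) applied to the daily mean temperature in
        the GDD calculation.
    y_max:
        Assumed maximum achievable field-scale tiller density
        (tillers ha^-1): 3 tillers per plant at 100000 plants ha^-1.
    pre_sow_days:
        Length (days) of the pre-sowing window included in cumulative
        moisture, to approximate soil water at planting.
    prob_threshold:
        Probability level at which limiting / non-limiting covariate
        thresholds are read off the response curves.
    gdd_cap_on:
        Where the 30 °C cap is applied: ``"mean"`` caps the daily mean
        temperature (default); ``"tmax"`` caps the daily maximum before
        averaging (a common agronomic variant).
    n_depth_cm / p_depth_cm:
        Soil sampling depths (cm) used for NO3/NH4 (0-60 cm) and for P and
        the remaining chemistry (0-15 cm).
    """

    t_base: float = 10.0
    t_cap: float = 30.0
    y_max: int = 300_000
    pre_sow_days: int = 30
    prob_threshold: float = 0.50
    gdd_cap_on: str = "mean"
    n_depth_cm: float = 60.0
    p_depth_cm: float = 15.0

    def __post_init__(self) -> None:
        if self.gdd_cap_on not in ("mean", "tmax"):
            raise ValueError(
                f"gdd_cap_on must be 'mean' or 'tmax', got {self.gdd_cap_on!r}"
            )
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.t_cap <= self.t_base:
            raise ValueError("t_cap must exceed t_base")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **kwargs) -> "Constants":
        return replace(self, **kwargs)


def load_constants(path: str | Path | None = None) -> Constants:
    """Load :class:`Constants`, optionally overridden from a YAML file.

    The YAML file may contain any subset of the Constants fields under a
    top-level ``constants:`` key (or at the top level directly).
    """
    if path is None:
        return Constants()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "constants" in raw:
        raw = raw["constants"] or {}
    known = set(Constants.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown constants in {path}: {sorted(unknown)}")
    return Constants(**raw)
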