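"""Limiting-threshold extraction from fitted response curves.

For a fitted model, traces the probability of attaining the maximum tiller
density as one covariate varies over its training support within a plant-
density class (all other covariates held at a reference policy, by default
the per-class training medians), smooths the curve with a centered moving
average, and reads off the covariate values where the smoothed probability
crosses 0.50 — rising crossings mark non-limiting-above thresholds, falling
crossings limiting-above ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tiller_gam import FACTOR_COLUMNS, NAME_TO_COLUMN, FittedTillerModel


@dataclass(frozen=True)
class ResponseCurve:
    """Per-covariate response trace within one plant-density class."""

    covariate: str                  # canonical name, e.g. "GDD"
    pd_class: str
    grid: np.ndarray                # strictly increasing covariate values
    probability: np.ndarray         # point-wise model probability
    smoothed: np.ndarray            # centered moving average

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for arr in (self.probability, self.smoothed):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.covariate, "pd_class": self.pd_class,
            "value": self.grid, "probability": self.probability,
            "smoothed": self.smoothed,
        })


@dataclass(frozen=True)
class ThresholdEstimate:
    """0.50-probability crossings of a smoothed response curve.

    ``crossings`` are covariate values sorted ascending; ``directions``
    holds "rising" (probability increases through the level: non-limiting
    above) or "falling" (limiting above) per crossing. ``none_flag`` marks
    curves that never cross the level.
    """

    covariate: str
    pd_class: str
    prob_level: float
    crossings: tuple[float, ...]
    directions: tuple[str, ...]

    @property
    def none_flag(self) -> bool:
        return len(self.crossings) == 0


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks near
    the boundaries so constants are preserved exactly)."""
    if window <= 1:
        return y.copy()
    n = len(y)
    half = window // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def response_curve(model: FittedTillerModel, covariate: str,
                   pd_class: str = "B", n_grid: int = 101,
                   ma_window: int = 11,
                   reference_policy: str = "class_median",
                   at_observed: np.ndarray | None = None) -> ResponseCurve:
    """Trace the fitted probability as ``covariate`` varies, holding all
    other covariates at reference values.

    ``reference_policy`` is ``"class_median"`` (per-pd_class training
    medians, the default) or ``"global_median"``. ``at_observed`` replaces
    the uniform grid with supplied (e.g. observed) covariate values.
    """
    if covariate not in NAME_TO_COLUMN:
        raise ValueError(f"unknown covariate {covariate!r}")
    column = NAME_TO_COLUMN[covariate]
    smooth_cols = {
        b.term_name for b in model._builder.blocks if b.basis is not None}
    if covariate not in smooth_cols:
        raise ValueError(
            f"{covariate!r} is not a smooth term of candidate "
            f"{model.spec.name!r}; smooth terms are {sorted(smooth_cols)}")
    if reference_policy not in ("class_median", "global_median"):
        raise ValueError(f"unknown reference policy {reference_policy!r}")

    stats = model.training_stats
    group = pd_class if reference_policy == "class_median" else "__all__"
    ref = stats[stats["pd_class"] == group].set_index("column")
    if ref.empty:
        raise ValueError(f"no training statistics for pd_class {pd_class!r}")
    support = stats[stats["pd_class"] == pd_class].set_index("column")
    lo, hi = support.loc[column, "min"], support.loc[column, "max"]
    if at_observed is not None:
        grid = np.unique(np.asarray(at_observed, float))
    else:
        grid = np.linspace(lo, hi, n_grid)

    frame = pd.DataFrame({c: np.full(len(grid), ref.loc[c, "median"])
                          for c in ref.index})
    frame[column] = grid
    frame["pd_class"] = pd_class
    # factor levels not being traced are held at their first training level
    for fac, col in FACTOR_COLUMNS.items():
        if col == "pd_class":
            continue
        for b in model._builder.blocks:
            if b.factor_levels is not None and b.term_name == fac:
                frame[col] = b.factor_levels[0]
    if "genotype" not in frame.columns:
        frame["genotype"] = "reference"

    prob = model.predict_proba(frame)
    smoothed = _moving_average(prob, ma_window)
    return ResponseCurve(covariate, pd_class, grid, prob, smoothed)


def extract_thresholds(curve: ResponseCurve,
                       prob: float = 0.50) -> ThresholdEstimate:
    """Locate the covariate values where the smoothed curve crosses ``prob``
    by linear interpolation between bracketing grid points; every crossing
    is reported with its direction. A curve that never reaches the level
    yields the none-flag (no crossings)."""
    if len(curve.grid) < 3:
        raise ValueError("threshold extraction needs >= 3 grid points")
    x, y = curve.grid, curve.smoothed
    crossings: list[float] = []
    directions: list[str] = []
    for i in range(len(x) - 1):
        y0, y1 = y[i] - prob, y[i + 1] - prob
        if y0 == 0.0 and (i == 0 or (y[i - 1] - prob) * y1 < 0):
            crossings.append(float(x[i]))
            directions.append("rising" if y1 > 0 else "falling")
        elif y0 * y1 < 0:
            t = y0 / (y0 - y1)
            crossings.append(float(x[i] + t * (x[i + 1] - x[i])))
            directions.append("rising" if y1 > y0 else "falling")
    return ThresholdEstimate(curve.covariate, curve.pd_class, prob,
                             tuple(crossings), tuple(directions))


def threshold_table(model: FittedTillerModel, covariates: list[str],
                    pd_classes: tuple[str, ...] = ("A", "B", "C"),
                    prob: float = 0.50, **curve_kwargs) -> pd.DataFrame:
    """Tidy table of all 0.50-probability crossings for the given covariates
    and density classes."""
    rows = []
    for cov in covariates:
        for cls in pd_classes:
            est = extract_thresholds(
                response_curve(model, cov, pd_class=cls, **curve_kwargs), prob)
            if est.none_flag:
                rows.append({"covariate": cov, "pd_class": cls,
                             "crossing": np.nan, "direction": "none"})
            for c, d in zip(est.crossings, est.directions):
                rows.append({"covariate": cov, "pd_class": cls,
                             "crossing": c, "direction": d})
    return pd.DataFrame(rows)
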