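"""Dataset splitting, candidate ranking, and out-of-season error attribution.

Two evaluation regimes: the "cross-season" regime splits all observations
80/20 (stratified by site-year) and ranks the candidate term sets by mean
absolute error of held-out tiller-density predictions; the "out-of-season"
regime holds out each season in turn, predicts each test site-year's
physiological-maturity (R6) tiller density at the 42000 plants ha^-1
reference class, and attributes excess error to individual model terms by
independently zeroing each term's coefficient block and recording which
exclusion most reduces the error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Constants
from .tiller_gam import FittedTillerModel, ModelSpec, fit

log = logging.getLogger("tillerscope")

#: Acceptable-error benchmark at the 42000 plants ha^-1 target (25% of it).
DEFAULT_ERROR_THRESHOLD = 10_500.0


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """A train/test partition of observation row indices."""

    mode: str                       # "cross_season" | "out_of_season"
    train: np.ndarray
    test: np.ndarray
    held_out_season: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")

    @property
    def train_fraction(self) -> float:
        return len(self.train) / (len(self.train) + len(self.test))


def cross_season_split(frame: pd.DataFrame, fraction: float = 0.8,
                       seed: int = 0) -> SplitPlan:
    """Random 80/20 (by default) split, stratified by site-year so every
    site-year is similarly represented in both sets. Reproducible from the
    seed."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, grp in frame.groupby("site_year", sort=True):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return SplitPlan("cross_season", np.sort(np.array(train_idx)),
                     np.sort(np.array(test_idx)), seed=seed)


def out_of_season_splits(frame: pd.DataFrame) -> list[SplitPlan]:
    """One plan per season: test = that season, train = all other seasons."""
    seasons = sorted(frame["season"].unique())
    if len(seasons) < 2:
        raise ValueError("out-of-season evaluation needs >= 2 distinct seasons")
    plans = []
    for season in seasons:
        mask = (frame["season"] == season).to_numpy()
        plans.append(SplitPlan(
            "out_of_season",
            train=frame.index.to_numpy()[~mask],
            test=frame.index.to_numpy()[mask],
            held_out_season=int(season),
        ))
    return plans


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def mae_mbe(predicted, observed) -> tuple[float, float]:
    """Mean absolute error and mean bias error (predicted - observed, so a
    positive bias is over-prediction), on the tiller-density scale."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size == 0:
        raise ValueError("error metrics need at least one prediction")
    err = predicted - observed
    return float(np.mean(np.abs(err))), float(np.mean(err))


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Held-out error per candidate, ranked ascending by MAE."""

    table: pd.DataFrame             # candidate, mae, mbe, n_test, rank, fitted
    selected: str
    split: SplitPlan
    models: dict[str, FittedTillerModel] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_candidates(registry: dict[str, ModelSpec], split: SplitPlan,
                    frame: pd.DataFrame, consts: Constants = Constants(),
                    family: str = "quasibinomial",
                    keep_models: bool = False) -> EvaluationReport:
    """Fit every candidate on the training rows, score MAE/MBE on the test
    rows, and rank ascending by MAE (registry order breaks ties).

    Candidates that fail to fit are kept in the report with infinite MAE and
    a logged warning; if all fail, an error is raised.
    """
    if split.mode != "cross_season":
        raise ValueError("rank_candidates expects a cross_season split")
    train = frame.loc[split.train]
    test = frame.loc[split.test]
    observed = test["tiller_density"].to_numpy(float)

    rows = []
    models: dict[str, FittedTillerModel] = {}
    for order, (name, spec) in enumerate(registry.items()):
        try:
            model = fit(spec, train, consts=consts, family=family)
            mae, mbe = mae_mbe(model.predict_density(test), observed)
            fitted = True
            if keep_models:
                models[name] = model
        except Exception as err:  # noqa: BLE001 - any fit failure demotes the candidate
            warnings.warn(f"candidate {name!r} failed to fit: {err}", stacklevel=2)
            log.warning("candidate %s failed to fit: %s", name, err)
            mae, mbe, fitted = np.inf, np.nan, False
        rows.append({"candidate": name, "mae": mae, "mbe": mbe,
                     "n_test": len(test), "order": order, "fitted": fitted})
    table = pd.DataFrame(rows)
    if not table["fitted"].any():
        raise RuntimeError("every candidate failed to fit")
    table = table.sort_values(["mae", "order"], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.drop(columns="order")
    selected = table.iloc[0]["candidate"]
    log.info("ranked %d candidates on %d test rows; selected %s (MAE %.0f)",
             len(table), len(test), selected, table.iloc[0]["mae"])
    return EvaluationReport(table=table, selected=selected, split=split,
                            models=models)


# ---------------------------------------------------------------------------
# out-of-season attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionTable:
    """Per-site-year error attribution plus its summary statistics.

    ``table`` columns: held_out_season, site_year, observed, predicted,
    full_error, best_excluded_term (empty string when no single-term
    exclusion improves on the full model), lowest_error.
    """

    table: pd.DataFrame
    threshold: float
    term_errors: pd.DataFrame | None = None   # long: season, site_year, term, error

    def summarize(self) -> dict:
        return summarize_attribution(self.table, self.threshold)

    def season_best_excluded(self) -> pd.DataFrame:
        """Per held-out season: the single exclusion that most reduces the
        season-level MAE of the point predictions, with the MAE before and
        after (term "" = no exclusion)."""
        if self.term_errors is None:
            raise ValueError("attribution table carries no per-term errors")
        rows = []
        for season, grp in self.term_errors.groupby("held_out_season"):
            mae_by_term = grp.groupby("term")["error"].mean()
            full_mae = mae_by_term[""]
            best = mae_by_term.idxmin()
            rows.append({
                "held_out_season": season,
                "full_mae": float(full_mae),
                "best_excluded_term": best if mae_by_term[best] < full_mae else "",
                "lowest_mae": float(mae_by_term.min()),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize_attribution(table: pd.DataFrame,
                          threshold: float = DEFAULT_ERROR_THRESHOLD) -> dict:
    """Summary of an attribution table: the percentage of site-years whose
    lowest achievable error falls below the acceptable-error threshold, and
    each season's share of the site-years that remain above it.

    Works on any table with ``lowest_error`` and ``held_out_season`` columns,
    including published ones.
    """
    low = table["lowest_error"].to_numpy(float)
    below = low < threshold
    n = len(table)
    share_by_season = {}
    n_fail = int((~below).sum())
    if n_fail:
        fails = table.loc[~below, "held_out_season"]
        for season, cnt in fails.value_counts().items():
            share_by_season[int(season)] = 100.0 * cnt / n_fail
    return {
        "n_site_years": n,
        "n_below_threshold": int(below.sum()),
        "percent_below_threshold": 100.0 * below.sum() / n,
        "n_above_threshold": n_fail,
        "failure_share_by_season": share_by_season,
        "threshold": float(threshold),
    }


def _reference_rows(test: pd.DataFrame, site_year: str, stage: str,
                    pd_class: str) -> pd.DataFrame:
    sub = test[(test["site_year"] == site_year)
               & (test["stage"] == stage)
               & (test["pd_class"] == pd_class)]
    return sub


def attribute_errors(models: dict[int, FittedTillerModel],
                     splits: list[SplitPlan], frame: pd.DataFrame,
                     stage: str = "R6", pd_class: str = "B",
                     threshold: float = DEFAULT_ERROR_THRESHOLD) -> AttributionTable:
    """Out-of-season coefficient-zeroing error attribution.

    For every held-out season and each of its site-years: take the test
    observations at physiological maturity (stage R6) in the reference
    plant-density class (B, the 42000 plants ha^-1 target; several plots are
    averaged), compute the full-model absolute error of the point
    prediction, then re-predict with each model term's coefficient block
    independently zeroed and record the exclusion that minimizes the error.
    The no-exclusion case is always a candidate, so the lowest error never
    exceeds the full error. Site-years without a qualifying observation are
    skipped with a warning.

    ``models`` maps held-out season -> the model trained on the remaining
    seasons (as produced by fitting on each plan in ``splits``).
    """
    rows = []
    long_rows = []
    for plan in splits:
        if plan.mode != "out_of_season":
            raise ValueError("attribute_errors expects out_of_season splits")
        season = plan.held_out_season
        if season not in models:
            raise KeyError(f"no fitted model for held-out season {season}")
        model = models[season]
        test = frame.loc[plan.test]
        for site_year in sorted(test["site_year"].unique()):
            ref = _reference_rows(test, site_year, stage, pd_class)
            if ref.empty:
                warnings.warn(
                    f"site-year {site_year!r} has no {stage} observation in "
                    f"density class {pd_class}; skipped", stacklevel=2)
                continue
            observed = float(ref["tiller_density"].mean())
            predicted = float(model.predict_density(ref).mean())
            full_error = abs(predicted - observed)
            long_rows.append({"held_out_season": season, "site_year": site_year,
                              "term": "", "error": full_error})
            best_term, lowest = "", full_error
            for term in model.term_names:
                pred_z = float(model.zero_term(term).predict_density(ref).mean())
                err_z = abs(pred_z - observed)
                long_rows.append({"held_out_season": season,
                                  "site_year": site_year, "term": term,
                                  "error": err_z})
                if err_z < lowest:
                    best_term, lowest = term, err_z
            rows.append({
                "held_out_season": season, "site_year": site_year,
                "observed": observed, "predicted": predicted,
                "full_error": full_error,
                "best_excluded_term": best_term, "lowest_error": lowest,
            })
    table = pd.DataFrame(rows)
    return AttributionTable(table=table, threshold=threshold,
                            term_errors=pd.DataFrame(long_rows))


def fit_out_of_season(spec: ModelSpec, splits: list[SplitPlan],
                      frame: pd.DataFrame, consts: Constants = Constants(),
                      family: str = "quasibinomial") -> dict[int, FittedTillerModel]:
    """Fit the selected structure once per out-of-season plan."""
    models = {}
    for plan in splits:
        models[plan.held_out_season] = fit(
            spec, frame.loc[plan.train], consts=consts, family=family)
        log.info("fitted %s without season %s (train fraction %.0f%%)",
                 spec.name, plan.held_out_season, 100 * plan.train_fraction)
    return models
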