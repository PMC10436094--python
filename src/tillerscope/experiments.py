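"""Reference experiments: seeded end-to-end checks of the pipeline on
synthetic data with known truth.

Each function generates its own data, runs the relevant pipeline stage, and
returns the measured quantities (recovery errors, attribution hit rates,
ranking wins, interval coverage). They are shared between the test suite and
the reproduction script so the numbers reported in both places come from the
same computation.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd

from .evaluation import (
    attribute_errors, cross_season_split, fit_out_of_season, mae_mbe,
    out_of_season_splits, rank_candidates,
)
from .synthetic_data import scenario_presets, generate
from .thresholds import extract_thresholds, response_curve
from .tiller_gam import ModelSpec, Term, candidate_registry, fit

GDD_ONLY = ModelSpec("GDD_only", (Term("GDD", "smooth"),))


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def null_signal_recovery(seed: int) -> dict:
    """Fit a smooth model to constant-probability data (n ~ 2000) and
    measure how far the intercept sits from logit(p) and how large the
    spurious smooth effects are on the logit scale."""
    cfg, truth = scenario_presets()["null"]
    cfg = dataclasses.replace(cfg, n_sites_per_season=11)   # ~1980 plots
    data = generate(cfg, truth, seed=seed)
    frame = data["frame"]
    model = fit(candidate_registry()["Temporal"], frame)
    p0 = 1.0 / (1.0 + np.exp(-truth.intercepts["B"]))
    intercept = model.coefficient_blocks()["intercept"][0]
    smooth_eta = model.zero_term("intercept").linear_predictor(frame)
    return {
        "n": len(frame),
        "intercept_abs_error": float(abs(intercept - np.log(p0 / (1 - p0)))),
        "max_smooth_effect": float(np.abs(smooth_eta).max()),
    }


def gdd_threshold_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Function and 0.50-threshold recovery on the sharp thermal-time
    scenario at n ~ 5000, across seeds.

    Measures the mean absolute deviation between the fitted and the true
    probability curve over the central 90% of the thermal-time range, and
    the distance of the recovered 0.50-crossing from the planted 200 °C day
    threshold as a fraction of the range.
    """
    cfg0, truth = scenario_presets()["gdd_step"]
    cfg = dataclasses.replace(cfg0, n_sites_per_season=11, n_reps=5)  # ~4950
    eff = truth.effects[0]

    def true_prob(g):
        z = eff.amp * (2.0 / (1.0 + np.exp(-(np.asarray(g) - eff.loc) / eff.scale)) - 1.0)
        return 1.0 / (1.0 + np.exp(-z))

    mads, cross_errs = [], []
    n_used = 0
    for s in _spawn(seed, n_seeds):
        data = generate(cfg, truth, seed=s)
        frame = data["frame"]
        n_used = len(frame)
        model = fit(GDD_ONLY, frame)
        lo, hi = frame["gdd"].min(), frame["gdd"].max()
        span = hi - lo
        grid = np.linspace(lo + 0.05 * span, hi - 0.05 * span, 200)
        ref = pd.concat([frame.iloc[:1]] * len(grid), ignore_index=True)
        ref["gdd"] = grid
        mads.append(float(np.abs(model.predict_proba(ref) - true_prob(grid)).mean()))
        est = extract_thresholds(response_curve(model, "GDD", pd_class="B"))
        rising = [c for c, d in zip(est.crossings, est.directions) if d == "rising"]
        if rising:
            cross_errs.append(min(abs(c - eff.loc) for c in rising) / span)
        else:
            cross_errs.append(np.inf)
    return {
        "n": n_used, "n_seeds": n_seeds,
        "mad_per_seed": mads, "max_mad": float(max(mads)),
        "crossing_error_frac_per_seed": cross_errs,
        "max_crossing_error_frac": float(max(cross_errs)),
        "planted_threshold": eff.loc,
    }


def attribution_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Out-of-season attribution on the season-shifted scenario: how often
    the planted season-inconsistent term (soil NO3) is the exclusion that
    most reduces the held-out season's MAE, and the MAE before/after."""
    cfg, truth = scenario_presets()["season_shift"]
    planted = "NO3"
    held_out = 2021          # the season in which the planted effect is absent
    hits = 0
    full_maes, zeroed_maes = [], []
    n_used = 0
    for s in _spawn(seed, n_replicates):
        data = generate(cfg, truth, seed=s)
        frame = data["frame"]
        n_used = len(frame)
        splits = [p for p in out_of_season_splits(frame)
                  if p.held_out_season == held_out]
        models = fit_out_of_season(candidate_registry()["ExM"], splits, frame)
        attr = attribute_errors(models, splits, frame)
        best = attr.season_best_excluded().iloc[0]
        hits += best.best_excluded_term == planted
        by_term = attr.term_errors.groupby("term")["error"].mean()
        full_maes.append(float(by_term[""]))
        zeroed_maes.append(float(by_term[planted]))
    return {
        "n": n_used, "n_replicates": n_replicates, "hits": hits,
        "hit_rate_pct": 100.0 * hits / n_replicates,
        "mean_full_mae": float(np.mean(full_maes)),
        "mean_mae_after_exclusion": float(np.mean(zeroed_maes)),
        "planted_term": planted,
    }


def ranking_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Cross-season candidate ranking on the density-interaction scenario:
    how often the ExM candidate out-ranks the Soil-only candidate."""
    cfg, truth = scenario_presets()["exm"]
    reg = candidate_registry()
    sub = {k: reg[k] for k in ("ExM", "Soil")}
    wins = 0
    exm_maes, soil_maes = [], []
    n_used = 0
    for s in _spawn(seed, n_replicates):
        data = generate(cfg, truth, seed=s)
        frame = data["frame"]
        n_used = len(frame)
        split = cross_season_split(frame, seed=s)
        report = rank_candidates(sub, split, frame)
        table = report.table.set_index("candidate")
        exm_maes.append(float(table.loc["ExM", "mae"]))
        soil_maes.append(float(table.loc["Soil", "mae"]))
        wins += table.loc["ExM", "mae"] < table.loc["Soil", "mae"]
    return {
        "n": n_used, "n_replicates": n_replicates, "wins": int(wins),
        "mean_exm_mae": float(np.mean(exm_maes)),
        "mean_soil_mae": float(np.mean(soil_maes)),
    }


def interval_coverage(seed: int, n_replicates: int = 20,
                      points_per_replicate: int = 25) -> dict:
    """Empirical coverage of the 0.95 quantile prediction interval for new
    observations of a well-specified model (coefficient uncertainty plus
    dispersion-scaled sampling noise)."""
    cfg, truth = scenario_presets()["gdd_step"]
    inside = total = 0
    for s in _spawn(seed, n_replicates):
        data = generate(cfg, truth, seed=s)
        frame = data["frame"]
        model = fit(GDD_ONLY, frame)
        test = frame.sample(points_per_replicate, random_state=s % (2**31 - 1))
        lo, hi = model.prediction_interval(test, n_draws=800, seed=s,
                                           sampling_noise=True)
        obs = test["tiller_density"].to_numpy()
        inside += int(((obs >= lo) & (obs <= hi)).sum())
        total += len(obs)
    return {"n_predictions": total, "coverage": inside / total}


def determinism_check(seed: int) -> dict:
    """Generate, derive covariates, fit and predict twice under the same
    seed; compare checksums of every stage's output."""
    digests = []
    for _ in range(2):
        cfg, truth = scenario_presets()["exm"]
        data = generate(cfg, truth, seed=seed)
        frame = data["frame"]
        model = fit(candidate_registry()["ExM"], frame)
        pred = model.predict_density(frame)
        lo, hi = model.prediction_interval(frame.iloc[:10], n_draws=400, seed=seed)
        h = hashlib.sha256()
        h.update(data["observations"].to_csv(index=False).encode())
        h.update(frame.to_csv(index=False).encode())
        h.update(np.ascontiguousarray(pred).tobytes())
        h.update(np.ascontiguousarray(lo).tobytes())
        h.update(np.ascontiguousarray(hi).tobytes())
        digests.append(h.hexdigest())
    return {"identical": digests[0] == digests[1], "checksum": digests[0]}
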