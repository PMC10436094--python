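"""Splitting, error metrics, candidate ranking and error attribution."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import tillerscope as ts
from tillerscope.reference_data import published_attribution_table


def _toy_frame(n=100, n_sites=5, seed=0):
    rng = np.random.default_rng(seed)
    sites = [f"S{i} 2020" for i in range(n_sites)]
    return pd.DataFrame({
        "site_year": np.resize(np.repeat(sites, max(n // n_sites, 1)), n),
        "season": 2020,
        "tiller_density": rng.uniform(0, 100000, n),
    })


class TestCrossSeasonSplit:
    def test_eighty_twenty(self):
        plan = ts.cross_season_split(_toy_frame(100), fraction=0.8, seed=1)
        assert len(plan.train) == 80 and len(plan.test) == 20

    def test_reproducible(self):
        f = _toy_frame(100)
        a = ts.cross_season_split(f, seed=4)
        b = ts.cross_season_split(f, seed=4)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_partition(self):
        f = _toy_frame(97)
        plan = ts.cross_season_split(f, seed=2)
        assert set(plan.train) | set(plan.test) == set(f.index)
        assert not set(plan.train) & set(plan.test)

    def test_stratified_by_site_year(self):
        f = _toy_frame(200, n_sites=8)
        for seed in range(50):
            plan = ts.cross_season_split(f, seed=seed)
            test = f.loc[plan.test]
            for _, grp in f.groupby("site_year"):
                share = len(test[test.site_year == grp.site_year.iloc[0]]) / len(grp)
                assert abs(share - 0.2) <= 0.10

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            ts.cross_season_split(_toy_frame(), fraction=1.2)


class TestOutOfSeasonSplits:
    def test_one_plan_per_season_partition(self, gdd_step_data):
        frame = gdd_step_data["frame"]
        plans = ts.out_of_season_splits(frame)
        assert len(plans) == 3
        test_union = np.concatenate([p.test for p in plans])
        assert sorted(test_union) == sorted(frame.index)
        for p in plans:
            assert set(frame.loc[p.test, "season"]) == {p.held_out_season}
            assert p.held_out_season not in set(frame.loc[p.train, "season"])

    def test_single_season_rejected(self):
        with pytest.raises(ValueError, match="2"):
            ts.out_of_season_splits(_toy_frame())

    def test_train_fractions_reported(self, gdd_step_data):
        plans = ts.out_of_season_splits(gdd_step_data["frame"])
        for p in plans:
            assert 0.5 < p.train_fraction < 0.9


class TestMaeMbe:
    def test_signed_examples(self):
        mae, mbe = ts.mae_mbe([13, 5], [10, 10])
        assert (mae, mbe) == (4.0, -1.0)

    def test_perfect(self):
        assert ts.mae_mbe([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        pred, obs = rng.normal(size=50), rng.normal(size=50)
        mae, mbe = ts.mae_mbe(pred, obs)
        assert mae == pytest.approx(sum(abs(p - o) for p, o in zip(pred, obs)) / 50)
        assert mbe == pytest.approx(sum(p - o for p, o in zip(pred, obs)) / 50)
        assert mae >= abs(mbe)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.mae_mbe([], [])


class TestRankCandidates:
    def test_single_candidate_selected(self, gdd_step_data, gdd_only_spec):
        frame = gdd_step_data["frame"]
        split = ts.cross_season_split(frame, seed=0)
        rep = ts.rank_candidates({"GDD_only": gdd_only_spec}, split, frame)
        assert len(rep.table) == 1
        assert rep.selected == "GDD_only"

    def test_identical_candidates_tie_in_registry_order(self, gdd_step_data,
                                                        gdd_only_spec):
        frame = gdd_step_data["frame"]
        split = ts.cross_season_split(frame, seed=0)
        twin = dataclasses.replace(gdd_only_spec, name="twin")
        rep = ts.rank_candidates({"first": gdd_only_spec, "twin": twin},
                                 split, frame)
        assert rep.table.mae.iloc[0] == rep.table.mae.iloc[1]
        assert list(rep.table.candidate) == ["first", "twin"]

    def test_order_invariant_up_to_ties(self, gdd_step_data, gdd_only_spec):
        frame = gdd_step_data["frame"]
        split = ts.cross_season_split(frame, seed=0)
        reg = ts.candidate_registry()
        sub = {k: reg[k] for k in ("Temporal", "Stress")}
        fwd = ts.rank_candidates(sub, split, frame)
        rev = ts.rank_candidates(dict(reversed(sub.items())), split, frame)
        assert dict(zip(fwd.table.candidate, fwd.table.mae.round(6))) == \
               dict(zip(rev.table.candidate, rev.table.mae.round(6)))

    def test_failing_candidate_demoted_with_warning(self, gdd_step_data,
                                                    gdd_only_spec):
        frame = gdd_step_data["frame"]
        split = ts.cross_season_split(frame, seed=0)
        broken = ts.ModelSpec("broken", (ts.Term("CEC", "smooth", k=10),))
        tiny = frame.copy()
        tiny["cec"] = 11.0          # constant covariate cannot be smoothed
        with pytest.warns(UserWarning, match="broken"):
            rep = ts.rank_candidates(
                {"GDD_only": gdd_only_spec, "broken": broken},
                ts.cross_season_split(tiny, seed=0), tiny)
        row = rep.table.set_index("candidate").loc["broken"]
        assert np.isinf(row.mae) and not row.fitted
        assert rep.selected == "GDD_only"

    def test_requires_cross_season_plan(self, gdd_step_data, gdd_only_spec):
        plans = ts.out_of_season_splits(gdd_step_data["frame"])
        with pytest.raises(ValueError, match="cross_season"):
            ts.rank_candidates({"g": gdd_only_spec}, plans[0],
                               gdd_step_data["frame"])


class TestAttributionSummary:
    def test_published_table_summary(self):
        """The published per-site-year lowest errors with the 10500
        threshold: 10 of 17 site-years pass (59%), and 2020 holds 5 of the
        7 remaining failures (71%)."""
        table = published_attribution_table()
        summary = ts.summarize_attribution(table, threshold=10_500)
        assert summary["n_site_years"] == 17
        assert summary["n_below_threshold"] == 10
        assert summary["percent_below_threshold"] == pytest.approx(58.82, abs=0.01)
        assert summary["failure_share_by_season"][2020] == pytest.approx(71.43, abs=0.01)

    def test_published_full_error_ranges(self):
        """Season-wise min/max of the published full-model errors."""
        table = published_attribution_table()
        r = table.groupby("held_out_season")["full_error"].agg(["min", "max"])
        assert tuple(r.loc[2019]) == (7211, 23795)
        assert tuple(r.loc[2020]) == (19574, 280461)
        assert tuple(r.loc[2021]) == (2564, 40372)

    def test_lowest_never_exceeds_full(self):
        table = published_attribution_table()
        assert (table.lowest_error <= table.full_error).all()


@pytest.fixture(scope="module")
def attribution_run():
    cfg, truth = ts.scenario_presets()["season_shift"]
    cfg = dataclasses.replace(cfg, n_sites_per_season=5)
    data = ts.generate(cfg, truth, seed=77)
    frame = data["frame"]
    splits = [p for p in ts.out_of_season_splits(frame)
              if p.held_out_season == 2021]
    models = ts.fit_out_of_season(ts.candidate_registry()["ExM"], splits, frame)
    return ts.attribute_errors(models, splits, frame), frame


class TestAttributeErrors:
    def test_lowest_bounded_by_full(self, attribution_run):
        table = attribution_run[0].table
        assert (table.lowest_error <= table.full_error + 1e-9).all()
        assert len(table) == 5

    def test_empty_best_term_means_no_improvement(self, attribution_run):
        table = attribution_run[0].table
        for _, row in table.iterrows():
            if row.best_excluded_term == "":
                assert row.lowest_error == pytest.approx(row.full_error)

    def test_season_best_consistent_with_term_errors(self, attribution_run):
        attr, _ = attribution_run
        sb = attr.season_best_excluded()
        te = attr.term_errors
        mae_by_term = te.groupby("term")["error"].mean()
        assert sb.iloc[0].lowest_mae == pytest.approx(mae_by_term.min())

    def test_site_year_without_reference_is_skipped(self, attribution_run):
        attr, frame = attribution_run
        drop_site = frame[frame.season == 2021].site_year.iloc[0]
        reduced = frame[~((frame.site_year == drop_site)
                          & (frame.stage == "R6"))]
        splits = [p for p in ts.out_of_season_splits(reduced)
                  if p.held_out_season == 2021]
        models = ts.fit_out_of_season(
            ts.candidate_registry()["Temporal"], splits, reduced)
        with pytest.warns(UserWarning, match=str(drop_site)):
            out = ts.attribute_errors(models, splits, reduced)
        assert drop_site not in set(out.table.site_year)


class TestNoiseFloor:
    def test_mae_approaches_gaussian_noise_floor(self):
        """With Gaussian density-scale noise and a well-specified model, the
        held-out MAE converges to sigma * sqrt(2/pi)."""
        cfg, _ = ts.scenario_presets()["gdd_step"]
        cfg = dataclasses.replace(cfg, n_sites_per_season=11, n_reps=3)
        truth = ts.TrueResponse(
            intercepts={c: -0.8 for c in "ABC"},
            effects=(), noise="gaussian", gauss_sd=8000.0)
        data = ts.generate(cfg, truth, seed=13)
        frame = data["frame"]
        split = ts.cross_season_split(frame, seed=13)
        spec = ts.ModelSpec("GDD_only", (ts.Term("GDD", "smooth"),))
        model = ts.fit(spec, frame.loc[split.train])
        test = frame.loc[split.test]
        mae, _ = ts.mae_mbe(model.predict_density(test),
                            test.tiller_density.to_numpy())
        floor = 8000.0 * np.sqrt(2 / np.pi)
        assert mae == pytest.approx(floor, rel=0.15)
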