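"""Shared fixtures: small deterministic datasets for every module."""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

import tillerscope as ts


def make_weather(start: date, n_days: int, t_min=15.0, t_max=29.0,
                 radiation=22.0, vpd=1.2, precip=2.0, irrigation=0.0,
                 site_year: str | None = None) -> pd.DataFrame:
    """A constant-valued daily weather frame (easy hand arithmetic)."""
    days = [start + timedelta(days=i) for i in range(n_days)]
    frame = pd.DataFrame({
        "date": days,
        "t_min": t_min, "t_max": t_max, "radiation": radiation,
        "vpd": vpd, "precip": precip, "irrigation": irrigation,
    })
    if site_year is not None:
        frame.insert(0, "site_year", site_year)
    return frame


@pytest.fixture(scope="session")
def soil():
    return ts.SoilProfile(ph=6.5, om=2.7, no3_conc=26.8, nh4_conc=2.1,
                          p_conc=52.1, cec=18.2, sand=20.0, silt=60.0,
                          clay=20.0, bulk_density=1.3)


@pytest.fixture(scope="session")
def null_data():
    """Constant-probability synthetic data, n ~ 2000 observations."""
    cfg, truth = ts.scenario_presets()["null"]
    cfg = dataclasses.replace(cfg, n_sites_per_season=11)
    return ts.generate(cfg, truth, seed=11)


@pytest.fixture(scope="session")
def gdd_step_data():
    """Sharp thermal-time threshold data at the default generator size."""
    cfg, truth = ts.scenario_presets()["gdd_step"]
    return ts.generate(cfg, truth, seed=7)


@pytest.fixture(scope="session")
def gdd_step_truth_curve():
    """The gdd_step planted response on a grid (for recovery checks)."""
    def curve(g):
        return 1.0 / (1.0 + np.exp(-(1.2 * (2.0 / (1.0 + np.exp(-(np.asarray(g) - 200.0) / 30.0)) - 1.0))))
    return curve


@pytest.fixture(scope="session")
def gdd_only_spec():
    return ts.ModelSpec("GDD_only", (ts.Term("GDD", "smooth"),))


@pytest.fixture(scope="session")
def exm_small():
    """One exm-preset dataset with its cross-season split."""
    cfg, truth = ts.scenario_presets()["exm"]
    data = ts.generate(cfg, truth, seed=21)
    split = ts.cross_season_split(data["frame"], seed=21)
    return data, split
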