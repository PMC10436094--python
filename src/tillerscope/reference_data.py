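"""Published field-study values used as worked-example inputs.

The multi-season Kansas corn tillering trial network this pipeline models
did not deposit its raw data, but its printed summary quantities and its
out-of-season error-attribution table are exactly recomputable inputs: the
attribution summarizer and the in-study arithmetic (acceptable-error
margins, the maximum-density assumption) operate on them directly.
"""

from __future__ import annotations

import pandas as pd

#: Mean observed plant density across the study (plants ha^-1).
MEAN_PLANT_DENSITY = 41_295
#: Observed plant-density range (plants ha^-1).
PLANT_DENSITY_RANGE = (17_514, 73_807)
#: Mean observed tiller density (tillers ha^-1).
MEAN_TILLER_DENSITY = 28_781
#: Highest observed tiller density (tillers ha^-1).
MAX_OBSERVED_TILLER_DENSITY = 152_842
#: Field-scale maximum-density assumption: tillers per plant x plants ha^-1.
MAX_TILLERS_PER_PLANT = 3
MAX_PLANT_DENSITY = 100_000

#: Published cross-season MAE (tillers ha^-1) per candidate (80/20 split).
PUBLISHED_CANDIDATE_MAE = {
    "Full": 9051, "Temporal": 13908, "Weather": 9362, "Soil": 19560,
    "E": 9362, "M": 11377, "Stress": 10605, "G+E": 9116, "GxE": 9736,
    "E+M": 9066, "ExM": 7776, "G+M": 22764, "GxM": 23131, "G+E+M": 9050,
    "GxExM": 10371,
}
#: Published mean bias error of the selected ExM candidate.
PUBLISHED_EXM_MBE = -38

#: Out-of-season error attribution by site-year: full-model absolute error,
#: the lowest error achievable by zeroing one coefficient block, and the
#: block zeroed (empty = no exclusion improved). Errors in tillers ha^-1.
_ATTRIBUTION_ROWS = [
    (2019, "Manhattan", 7211, 4099, "VPD"),
    (2019, "Goodland", 15003, 5963, "NO3"),
    (2019, "Garden City", 23795, 13366, "T_min"),
    (2020, "Keats", 280461, 10283, "P"),
    (2020, "Greensburg", 236793, 56352, "NO3"),
    (2020, "Goodland", 39840, 39840, ""),
    (2020, "Garden City", 19574, 19574, ""),
    (2020, "Colby B", 272656, 27344, "PTQ"),
    (2020, "Colby A", 42732, 27631, "P"),
    (2020, "Buhler", 191106, 1653, "P"),
    (2021, "Selkirk", 40372, 9770, "VPD"),
    (2021, "Keats", 9477, 7280, "GDD"),
    (2021, "Greensburg", 25012, 11851, "T_min"),
    (2021, "Goodland", 12594, 6547, "GDD"),
    (2021, "Garden City", 12847, 1058, "T_max"),
    (2021, "Colby A", 19507, 8579, "GDD"),
    (2021, "Buhler", 2564, 912, "VPD"),
]


def acceptable_error(plant_density: float) -> float:
    """The study's acceptable-error margin: 25% of a plant density,
    expressed in tillers ha^-1."""
    return 0.25 * plant_density


def published_attribution_table() -> pd.DataFrame:
    """The published per-site-year out-of-season attribution table, in the
    schema of :func:`tillerscope.evaluation.attribute_errors`."""
    return pd.DataFrame(
        _ATTRIBUTION_ROWS,
        columns=["held_out_season", "site_year", "full_error",
                 "lowest_error", "best_excluded_term"],
    )
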