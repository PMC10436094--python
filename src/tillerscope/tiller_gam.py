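"""Binomial GAM of the probability of attaining the maximum tiller density.

Tiller density y (tillers ha^-1) is modeled as y = m * 300000, where m is
the probability of attaining the assumed field-scale maximum of 300000
tillers ha^-1 (3 tillers per plant at 100000 plants ha^-1) and the response
is binomial with 300000 trials, encoded as a proportion with prior weight.
The linear predictor on the logit scale combines penalized thin-plate spline
smooths of the agroclimatic and soil covariates, optionally split by plant-
density class or genotype (factor-by smooths), plus categorical main
effects.

A declarative registry holds the 15 candidate term sets spanning genotype
(G), environment (E) and management (M) variable groups; the interaction
candidates use factor-by smooths (separate smooth per factor level), the
additive ones shared smooths plus categorical main effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Constants, PD_TARGETS
from .gam import PenalizedFit, SmoothBasis, fit_penalized_glm, tprs_basis

# canonical covariate names -> model-frame columns
NAME_TO_COLUMN: dict[str, str] = {
    "GDD": "gdd", "PTQ": "ptq", "T_min": "t_min_mean", "T_max": "t_max_mean",
    "T_amp": "t_amp_mean", "CM": "cm", "VPD": "vpd_cum", "PD": "observed_pd",
    "pH": "ph", "OM": "om", "NO3": "no3_kg", "NH4": "nh4_kg", "P": "p_kg",
    "CEC": "cec", "Sand": "sand", "Silt": "silt", "Clay": "clay",
}
FACTOR_COLUMNS: dict[str, str] = {"G": "genotype", "PD": "pd_class"}

INTERCEPT = "intercept"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinomialResponse:
    """Tiller density as binomial successes out of the assumed maximum."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError(
                f"successes {self.successes} outside [0, {self.trials}]; the "
                f"maximum-density assumption caps tiller density at the trial "
                f"count"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def make_response(tiller_density: float, consts: Constants = Constants()) -> BinomialResponse:
    """Encode an observed tiller density (tillers ha^-1) as a binomial draw
    with 300000 trials (successes = rounded density)."""
    if tiller_density < 0 or tiller_density > consts.y_max:
        raise ValueError(
            f"tiller density {tiller_density} violates the assumed maximum of "
            f"{consts.y_max} tillers ha^-1"
        )
    return BinomialResponse(successes=int(round(tiller_density)), trials=consts.y_max)


@dataclass(frozen=True)
class Term:
    """One model term: a penalized smooth (optionally factor-by) or a
    categorical main effect."""

    name: str                      # canonical covariate name (Table vocabulary)
    kind: str                      # "smooth" | "factor"
    by: str | None = None          # None | "pd_class" | "genotype" | "pd_class:genotype"
    k: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("smooth", "factor"):
            raise ValueError(f"term kind must be smooth or factor, got {self.kind!r}")
        if self.kind == "smooth" and self.name not in NAME_TO_COLUMN:
            raise ValueError(f"unknown smooth covariate {self.name!r}")
        if self.kind == "factor" and self.name not in FACTOR_COLUMNS:
            raise ValueError(f"unknown factor {self.name!r}")

    @property
    def column(self) -> str:
        return NAME_TO_COLUMN[self.name] if self.kind == "smooth" else FACTOR_COLUMNS[self.name]


@dataclass(frozen=True)
class ModelSpec:
    """A named candidate: its term list and default basis dimension."""

    name: str
    terms: tuple[Term, ...]
    basis_dim: int = 10

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


def _smooths(names, by=None, k=10):
    return tuple(Term(n, "smooth", by=by, k=k) for n in names)


def candidate_registry(basis_dim: int = 10) -> dict[str, ModelSpec]:
    """The 15 candidate term sets over the G / E / M variable groups.

    Interaction ("x") candidates involving plant density use factor-by
    smooths over the three density classes (A/B/C); those involving genotype
    use by-genotype smooths; the three-way candidate uses the combined
    pd_class x genotype factor. Every factor-by candidate also carries the
    factor's main effect.
    """
    k = basis_dim
    key_env = ("GDD", "PTQ", "T_min", "T_max", "VPD")   # simplified E set
    key_soil = ("NO3", "P")
    reg = {
        "Full": ModelSpec("Full", _smooths(
            ("GDD", "PTQ", "T_min", "T_max", "T_amp", "CM", "VPD", "PD",
             "pH", "OM", "NO3", "NH4", "P", "CEC", "Sand", "Silt", "Clay"), k=k)
            + (Term("G", "factor"),), k),
        "Temporal": ModelSpec("Temporal", _smooths(("GDD", "PTQ"), k=k), k),
        "Weather": ModelSpec("Weather", _smooths(
            ("GDD", "PTQ", "T_min", "T_max", "T_amp", "CM", "VPD"), k=k), k),
        "Soil": ModelSpec("Soil", _smooths(
            ("pH", "OM", "NO3", "NH4", "P", "CEC", "Sand", "Silt", "Clay"), k=k), k),
        "E": ModelSpec("E", _smooths(
            ("GDD", "T_min", "T_max", "T_amp", "CM", "VPD",
             "pH", "OM", "NO3", "NH4", "P", "CEC", "Sand", "Silt", "Clay"), k=k), k),
        "M": ModelSpec("M", _smooths(
            ("GDD", "CM", "PD", "pH", "NO3", "NH4", "P"), k=k)
            + (Term("G", "factor"),), k),
        "Stress": ModelSpec("Stress", _smooths(("T_min", "T_max", "CM", "VPD"), k=k), k),
        "G+E": ModelSpec("G+E", _smooths(key_env + key_soil, k=k)
                         + (Term("G", "factor"),), k),
        "GxE": ModelSpec("GxE", _smooths(key_env + key_soil, by="genotype", k=k)
                         + (Term("G", "factor"),), k),
        "E+M": ModelSpec("E+M", _smooths(key_env + ("PD",) + key_soil, k=k), k),
        "ExM": ModelSpec("ExM", _smooths(key_env + key_soil, by="pd_class", k=k)
                         + (Term("PD", "factor"),), k),
        "G+M": ModelSpec("G+M", _smooths(("PD",), k=k) + (Term("G", "factor"),), k),
        "GxM": ModelSpec("GxM", _smooths(("PD",), by="genotype", k=k)
                         + (Term("G", "factor"),), k),
        "G+E+M": ModelSpec("G+E+M", _smooths(key_env + ("PD",) + key_soil, k=k)
                           + (Term("G", "factor"),), k),
        "GxExM": ModelSpec("GxExM",
                           _smooths(key_env + key_soil, by="pd_class:genotype", k=k)
                           + (Term("PD", "factor"), Term("G", "factor")), k),
    }
    return reg


#: Candidates whose structure contains the E x M interaction.
EXM_FAMILY = ("ExM", "GxExM")


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------


def _null_space_penalty(sl: slice) -> tuple[slice, np.ndarray]:
    """Shrinkage penalty on a smooth's unpenalized linear column (the
    double-penalty device), so null-signal smooths can shrink fully to
    zero rather than retaining a spurious slope."""
    width = sl.stop - sl.start
    S = np.zeros((width, width))
    S[-1, -1] = 1.0
    return sl, S


def _by_values(frame: pd.DataFrame, by: str) -> pd.Series:
    if ":" in by:
        a, b = by.split(":")
        return frame[a].astype(str) + ":" + frame[b].astype(str)
    return frame[by].astype(str)


@dataclass
class _Block:
    """Bookkeeping for one coefficient block of the design matrix."""

    term_name: str            # canonical name ("GDD", "G", ...) or "intercept"
    label: str                # display label, e.g. "s(GDD):pd_class=A"
    sl: slice                 # columns of the full design
    basis: SmoothBasis | None = None
    by: str | None = None
    by_level: str | None = None
    factor_levels: tuple[str, ...] | None = None   # for factor blocks


class DesignBuilder:
    """Builds the full model matrix and penalty for a :class:`ModelSpec`,
    and re-evaluates it on new data for prediction."""

    def __init__(self, spec: ModelSpec, frame: pd.DataFrame):
        self.spec = spec
        self.blocks: list[_Block] = []
        self.n_col = 0
        self.train_ranges: dict[str, tuple[float, float]] = {}
        self._build(frame)

    def _check_pd_levels(self, frame: pd.DataFrame) -> None:
        present = set(frame["pd_class"].astype(str))
        missing = sorted(set(PD_TARGETS) - present)
        if missing:
            raise ValueError(
                f"plant-density class level(s) {missing} absent from the "
                f"training data; the design would be rank deficient"
            )

    def _build(self, frame: pd.DataFrame) -> None:
        cols: list[np.ndarray] = []
        pens: list[tuple[slice, np.ndarray]] = []
        n = len(frame)

        cols.append(np.ones((n, 1)))
        self.blocks.append(_Block(INTERCEPT, INTERCEPT, slice(0, 1)))
        self.n_col = 1

        for term in self.spec.terms:
            if term.kind == "factor":
                col = term.column
                if col == "pd_class":
                    self._check_pd_levels(frame)
                levels = tuple(sorted(frame[col].astype(str).unique()))
                if len(levels) < 2:
                    raise ValueError(
                        f"factor {term.name!r} has a single level "
                        f"{levels[0]!r} in the training data"
                    )
                dummies = np.column_stack([
                    (frame[col].astype(str) == lv).to_numpy(float)
                    for lv in levels[1:]
                ])
                sl = slice(self.n_col, self.n_col + dummies.shape[1])
                cols.append(dummies)
                self.blocks.append(_Block(term.name, f"{term.name}", sl,
                                          factor_levels=levels))
                self.n_col = sl.stop
            else:
                x_all = frame[term.column].to_numpy(float)
                self.train_ranges.setdefault(
                    term.column, (float(x_all.min()), float(x_all.max())))
                if term.by is None:
                    design, basis = self._term_basis(x_all, term)
                    sl = slice(self.n_col, self.n_col + design.shape[1])
                    cols.append(design)
                    pens.append((sl, basis.penalty))
                    pens.append(_null_space_penalty(sl))
                    self.blocks.append(_Block(term.name, f"s({term.name})", sl,
                                              basis=basis))
                    self.n_col = sl.stop
                else:
                    if "pd_class" in term.by:
                        self._check_pd_levels(frame)
                    byv = _by_values(frame, term.by)
                    for lv in sorted(byv.unique()):
                        mask = (byv == lv).to_numpy()
                        if mask.sum() < 3:
                            raise ValueError(
                                f"by-level {lv!r} of {term.by} has fewer than "
                                f"3 observations for s({term.name})"
                            )
                        sub_design, basis = self._term_basis(x_all[mask], term)
                        block = np.zeros((n, sub_design.shape[1]))
                        block[mask] = sub_design
                        sl = slice(self.n_col, self.n_col + block.shape[1])
                        cols.append(block)
                        pens.append((sl, basis.penalty))
                        pens.append(_null_space_penalty(sl))
                        self.blocks.append(_Block(
                            term.name, f"s({term.name}):{term.by}={lv}", sl,
                            basis=basis, by=term.by, by_level=lv))
                        self.n_col = sl.stop

        self.X = np.hstack(cols)
        self.penalty_blocks = pens
        self.S = np.zeros((self.n_col, self.n_col))
        for sl, pen in pens:
            self.S[sl, sl] = pen

    @staticmethod
    def _term_basis(x: np.ndarray, term: Term) -> tuple[np.ndarray, SmoothBasis]:
        n_unique = np.unique(x).size
        k = min(term.k, n_unique)
        if k < 4:
            raise ValueError(
                f"covariate {term.name} has only {n_unique} unique values; "
                f"at least 4 are needed for a smooth"
            )
        return tprs_basis(x, k=k)

    def evaluate(self, frame: pd.DataFrame) -> np.ndarray:
        """Model matrix for new data, matching the training layout."""
        n = len(frame)
        X = np.zeros((n, self.n_col))
        for block in self.blocks:
            if block.term_name == INTERCEPT:
                X[:, block.sl] = 1.0
            elif block.factor_levels is not None:
                col = FACTOR_COLUMNS[block.term_name]
                vals = frame[col].astype(str)
                unknown = sorted(set(vals) - set(block.factor_levels))
                if unknown:
                    raise ValueError(
                        f"unknown {block.term_name} level(s) {unknown}; "
                        f"training levels were {list(block.factor_levels)}"
                    )
                X[:, block.sl] = np.column_stack([
                    (vals == lv).to_numpy(float)
                    for lv in block.factor_levels[1:]
                ])
            else:
                colname = NAME_TO_COLUMN[block.term_name]
                x = frame[colname].to_numpy(float)
                if block.by is None:
                    X[:, block.sl] = block.basis.evaluate(x)
                else:
                    mask = (_by_values(frame, block.by) == block.by_level).to_numpy()
                    if mask.any():
                        X[np.ix_(mask, range(block.sl.start, block.sl.stop))] = \
                            block.basis.evaluate(x[mask])
        return X

    def extrapolation_mask(self, frame: pd.DataFrame) -> np.ndarray:
        """True where any smooth covariate lies outside its training range."""
        out = np.zeros(len(frame), bool)
        for col, (lo, hi) in self.train_ranges.items():
            x = frame[col].to_numpy(float)
            out |= (x < lo) | (x > hi)
        return out


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionResult:
    """One point prediction: probability of the maximum density, the implied
    tiller density, an optional 0.95 quantile interval, and whether the
    covariates lie outside the training support."""

    probability: float
    tiller_density: float
    lower: float | None = None
    upper: float | None = None
    extrapolated: bool = False


class FittedTillerModel:
    """A fitted candidate with named coefficient blocks.

    Supports prediction, whole-term coefficient zeroing (for the error-
    attribution procedure) and posterior simulation of prediction intervals.
    """

    def __init__(self, spec: ModelSpec, builder: DesignBuilder,
                 fit: PenalizedFit, consts: Constants,
                 training_stats: pd.DataFrame, family: str):
        self.spec = spec
        self._builder = builder
        self.beta = fit.beta.copy()
        self.covariance = fit.covariance
        self.lam = fit.lam
        self.edf = fit.edf
        self.deviance = fit.deviance
        self.phi = fit.phi
        self.family = family
        self.consts = consts
        self.n_train = fit.n_obs
        self.training_stats = training_stats
        self._zeroed: tuple[str, ...] = ()

    # -- introspection ------------------------------------------------------

    @property
    def term_names(self) -> list[str]:
        """Zeroable names: every distinct term plus the intercept."""
        seen: list[str] = []
        for b in self._builder.blocks:
            if b.term_name not in seen:
                seen.append(b.term_name)
        return seen

    def coefficient_blocks(self) -> dict[str, np.ndarray]:
        """Coefficients grouped by block label (one entry per smooth
        by-level, factor, and the intercept)."""
        return {b.label: self.beta[b.sl].copy() for b in self._builder.blocks}

    @property
    def summary(self) -> dict:
        return {
            "candidate": self.spec.name, "n_train": self.n_train,
            "deviance": self.deviance, "edf": self.edf, "lambda": self.lam,
            "dispersion": self.phi, "family": self.family,
            "smoothing_selector": "GCV",
            "zeroed_terms": list(self._zeroed),
        }

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        return self._builder.evaluate(frame) @ self.beta

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(frame)))

    def predict_density(self, frame: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(frame) * self.consts.y_max

    def predict(self, frame: pd.DataFrame, interval: bool = False,
                n_draws: int = 1000, seed: int | None = None,
                sampling_noise: bool = False) -> list[PredictionResult]:
        prob = self.predict_proba(frame)
        extra = self._builder.extrapolation_mask(frame)
        lower = upper = [None] * len(prob)
        if interval:
            lower, upper = self.prediction_interval(
                frame, n_draws=n_draws, seed=seed, sampling_noise=sampling_noise)
        return [
            PredictionResult(float(p), float(p * self.consts.y_max),
                             None if l is None else float(l),
                             None if u is None else float(u), bool(e))
            for p, l, u, e in zip(prob, lower, upper, extra)
        ]

    def prediction_interval(self, frame: pd.DataFrame, n_draws: int = 1000,
                            seed: int | None = None,
                            sampling_noise: bool = False
                            ) -> tuple[np.ndarray, np.ndarray]:
        """0.95 quantile interval on the tiller-density scale via draws from
        the approximate multivariate-normal coefficient posterior.

        With ``sampling_noise`` the draw of a new observation given each
        probability is added on top of coefficient uncertainty, using the
        fitted dispersion: for a quasibinomial fit the per-observation
        variance is ``phi * p(1-p)/trials`` (realized as a beta-binomial
        draw), which is what makes the interval a prediction interval for a
        new site-year observation rather than for its mean.
        """
        if self.covariance is None:
            raise ValueError("model carries no coefficient covariance")
        if n_draws < 200:
            raise ValueError("n_draws must be >= 200 for stable 0.95 quantiles")
        rng = np.random.default_rng(seed)
        X = self._builder.evaluate(frame)
        cov = self.covariance
        if not np.any(cov):
            eta = (X @ self.beta)[None, :].repeat(1, axis=0)
        else:
            jitter = 1e-10 * np.eye(cov.shape[0])
            try:
                L = np.linalg.cholesky(cov + jitter)
            except np.linalg.LinAlgError:
                vals, vecs = np.linalg.eigh(cov)
                L = vecs * np.sqrt(np.clip(vals, 0, None))
            draws = self.beta[None, :] + rng.standard_normal((n_draws, len(self.beta))) @ L.T
            eta = draws @ X.T
        prob = 1.0 / (1.0 + np.exp(-eta))
        dens = prob * self.consts.y_max
        if sampling_noise:
            trials = self.consts.y_max
            p = np.clip(prob, 1e-9, 1 - 1e-9)
            rho = max(self.phi - 1.0, 0.0) / (trials - 1)
            if rho > 0:
                a = (1 - rho) / rho
                p = rng.beta(p * a, (1 - p) * a)
            dens = rng.binomial(trials, np.clip(p, 0, 1)).astype(float)
        lower = np.quantile(dens, 0.025, axis=0)
        upper = np.quantile(dens, 0.975, axis=0)
        return lower, upper

    # -- term zeroing -------------------------------------------------------

    def zero_term(self, term_name: str) -> "FittedTillerModel":
        """A copy with the named term's entire coefficient block (all basis
        coefficients across all by-levels, or all factor contrasts, or the
        intercept) set to zero. No refit."""
        valid = self.term_names
        if term_name not in valid:
            raise KeyError(
                f"unknown term {term_name!r}; valid names are {valid}"
            )
        clone = FittedTillerModel.__new__(FittedTillerModel)
        clone.__dict__.update(self.__dict__)
        clone.beta = self.beta.copy()
        for b in self._builder.blocks:
            if b.term_name == term_name:
                clone.beta[b.sl] = 0.0
        clone._zeroed = tuple(dict.fromkeys(self._zeroed + (term_name,)))
        return clone

    def zero_all(self) -> "FittedTillerModel":
        m = self
        for name in self.term_names:
            m = m.zero_term(name)
        return m

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing JSON archive: spec, blocks, covariance, metadata."""
        blocks = []
        for b in self._builder.blocks:
            entry = {
                "term_name": b.term_name, "label": b.label,
                "start": b.sl.start, "stop": b.sl.stop,
                "by": b.by, "by_level": b.by_level,
                "factor_levels": list(b.factor_levels) if b.factor_levels else None,
            }
            if b.basis is not None:
                entry["basis"] = {
                    "knots": b.basis.knots.tolist(),
                    "rotation": b.basis.rotation.tolist(),
                    "x_shift": b.basis.x_shift, "x_scale": b.basis.x_scale,
                    "col_scale": b.basis.col_scale.tolist(),
                    "col_mean": b.basis.col_mean.tolist(),
                    "penalty": b.basis.penalty.tolist(), "k": b.basis.k,
                }
            blocks.append(entry)
        payload = {
            "schema": "tillerscope-model-v1",
            "spec": {
                "name": self.spec.name, "basis_dim": self.spec.basis_dim,
                "terms": [
                    {"name": t.name, "kind": t.kind, "by": t.by, "k": t.k}
                    for t in self.spec.terms
                ],
            },
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "lambda": self.lam, "edf": self.edf, "deviance": self.deviance,
            "phi": self.phi, "family": self.family, "n_train": self.n_train,
            "constants": self.consts.to_dict(),
            "train_ranges": {k: list(v) for k, v in self._builder.train_ranges.items()},
            "training_stats": self.training_stats.to_dict(orient="list"),
            "blocks": blocks,
            "zeroed": list(self._zeroed),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FittedTillerModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "tillerscope-model-v1":
            raise ValueError(f"unrecognized model archive schema in {path}")
        spec = ModelSpec(
            payload["spec"]["name"],
            tuple(Term(t["name"], t["kind"], by=t["by"], k=t["k"])
                  for t in payload["spec"]["terms"]),
            payload["spec"]["basis_dim"],
        )
        builder = DesignBuilder.__new__(DesignBuilder)
        builder.spec = spec
        builder.blocks = []
        builder.train_ranges = {k: (v[0], v[1])
                                for k, v in payload["train_ranges"].items()}
        for b in payload["blocks"]:
            basis = None
            if "basis" in b:
                raw = b["basis"]
                basis = SmoothBasis(
                    knots=np.array(raw["knots"]),
                    rotation=np.array(raw["rotation"]),
                    x_shift=raw["x_shift"], x_scale=raw["x_scale"],
                    col_scale=np.array(raw["col_scale"]),
                    col_mean=np.array(raw["col_mean"]),
                    penalty=np.array(raw["penalty"]), k=raw["k"],
                )
            builder.blocks.append(_Block(
                b["term_name"], b["label"], slice(b["start"], b["stop"]),
                basis=basis, by=b["by"], by_level=b["by_level"],
                factor_levels=tuple(b["factor_levels"]) if b["factor_levels"] else None,
            ))
        builder.n_col = max(b.sl.stop for b in builder.blocks)

        model = cls.__new__(cls)
        model.spec = spec
        model._builder = builder
        model.beta = np.array(payload["beta"])
        model.covariance = np.array(payload["covariance"])
        model.lam = payload["lambda"]
        model.edf = payload["edf"]
        model.deviance = payload["deviance"]
        model.phi = payload["phi"]
        model.family = payload["family"]
        model.consts = Constants(**payload["constants"])
        model.n_train = payload["n_train"]
        model.training_stats = pd.DataFrame(payload["training_stats"])
        model._zeroed = tuple(payload["zeroed"])
        return model


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _training_stats(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-pd_class and global min / median / max of every numeric predictor,
    used as the reference policy when tracing response curves."""
    numeric = [c for c in NAME_TO_COLUMN.values() if c in frame.columns]
    rows = []
    groups = [("__all__", frame)] + list(frame.groupby("pd_class"))
    for label, grp in groups:
        for col in numeric:
            x = grp[col].to_numpy(float)
            rows.append({"pd_class": str(label), "column": col,
                         "min": float(x.min()), "median": float(np.median(x)),
                         "max": float(x.max())})
    return pd.DataFrame(rows)


def fit(spec: ModelSpec, frame: pd.DataFrame,
        consts: Constants = Constants(), family: str = "quasibinomial",
        lam_grid: np.ndarray | None = None) -> FittedTillerModel:
    """Fit one candidate to a model frame (as built by
    :func:`tillerscope.covariates.build_covariate_table`).

    The fit is a penalized binomial likelihood on the logit scale with a
    GCV-selected shared smoothing parameter; it is fully deterministic.
    """
    required = {t.column for t in spec.terms} | {"tiller_density", "pd_class"}
    missing = sorted(required - set(frame.columns))
    if missing:
        raise ValueError(f"model frame is missing columns: {missing}")
    frame = frame.reset_index(drop=True)
    responses = [make_response(td, consts) for td in frame["tiller_density"]]
    y = np.array([r.proportion for r in responses])
    w = np.array([float(r.trials) for r in responses])

    builder = DesignBuilder(spec, frame)
    result = fit_penalized_glm(builder.X, y, w, builder.penalty_blocks,
                               family=family, lam_grid=lam_grid)
    return FittedTillerModel(spec, builder, result, consts,
                             _training_stats(frame), family)
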