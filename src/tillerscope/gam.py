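"""Penalized regression-spline engine for binomial generalized additive models.

Implements one-dimensional thin-plate regression splines (the low-rank
eigen-approximation of the full thin-plate spline), penalized iteratively
reweighted least squares (PIRLS) on the logit scale for binomial/quasibinomial
responses encoded as proportions with prior weights, and smoothing-parameter
selection by generalized cross-validation (GCV).

The thin-plate basis for a 1-D smooth of order m=2 uses the radial function
eta(r) = r^3 on covariates rescaled to [0, 1]. The full-rank spline
f(x) = sum_i delta_i eta(|x - x_i|) + a0 + a1 x, subject to the null-space
constraint T' delta = 0, is truncated to the k eigenvectors of the radial
matrix E with largest-magnitude eigenvalues; the constraint is absorbed by a
QR null-space rotation. The resulting basis carries k-2 penalized columns
(penalty = the diagonalized wiggliness measure) plus one unpenalized linear
column; the constant is left to the model intercept and all columns are
centered on the training data.

GCV is scale-invariant in the dispersion, so the same criterion serves the
binomial and the overdispersed quasibinomial case; the dispersion enters only
the coefficient covariance (Pearson estimate), which is what makes prediction
intervals honest under overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, qr

__all__ = [
    "SmoothBasis", "PenalizedFit", "tprs_basis", "fit_penalized_glm",
    "binomial_deviance",
]

_EPS_MU = 1e-8
_MAX_KNOTS = 200


# ---------------------------------------------------------------------------
# thin-plate regression-spline basis
# ---------------------------------------------------------------------------


@dataclass
class SmoothBasis:
    """A fitted 1-D thin-plate regression-spline basis.

    Stores everything needed to evaluate the basis at new covariate values:
    the knots (on the rescaled scale), the truncation/constraint rotation,
    the covariate rescaling, per-column scaling and the training column
    means removed for identifiability.
    """

    knots: np.ndarray          # rescaled knot locations
    rotation: np.ndarray       # (n_knots, k-2) combined U_k @ Z
    x_shift: float
    x_scale: float
    col_scale: np.ndarray      # (k-1,) column RMS normalization
    col_mean: np.ndarray       # (k-1,) training means (after scaling)
    penalty: np.ndarray        # (k-1, k-1) PSD penalty, unit Frobenius norm
    k: int

    @property
    def n_coef(self) -> int:
        return self.rotation.shape[1] + 1  # penalized columns + linear

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Design columns for new covariate values (centered as in training)."""
        xs = (np.asarray(x, float) - self.x_shift) / self.x_scale
        r = np.abs(xs[:, None] - self.knots[None, :])
        cols = (r ** 3) @ self.rotation
        design = np.column_stack([cols, xs])
        design /= self.col_scale
        design -= self.col_mean
        return design


def tprs_basis(x: np.ndarray, k: int = 10) -> tuple[np.ndarray, SmoothBasis]:
    """Construct the thin-plate regression-spline basis from training data.

    Parameters
    ----------
    x:
        Training covariate values.
    k:
        Basis dimension before constraint absorption; the returned design has
        ``k - 1`` columns (k-2 penalized + 1 linear).

    Returns
    -------
    design, basis:
        The centered training design (n, k-1) and the reusable basis object.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("a smooth needs a 1-D covariate with >= 3 values")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("covariate is constant; cannot build a smooth")
    xs = (x - lo) / (hi - lo)

    uniq = np.unique(xs)
    if uniq.size < k:
        raise ValueError(
            f"smooth basis dimension k={k} exceeds the {uniq.size} unique "
            "covariate values"
        )
    if uniq.size > _MAX_KNOTS:
        qs = np.linspace(0, 1, _MAX_KNOTS)
        knots = np.unique(np.quantile(uniq, qs))
    else:
        knots = uniq

    r = np.abs(knots[:, None] - knots[None, :])
    E = r ** 3
    evals, evecs = eigh(E)
    order = np.argsort(np.abs(evals))[::-1][:k]
    U = evecs[:, order]
    D = evals[order]

    # absorb the null-space constraint T' delta = 0, T = [1, knots]
    T = np.column_stack([np.ones_like(knots), knots])
    C = T.T @ U                                   # (2, k)
    Q, _ = qr(C.T, mode="full")
    Z = Q[:, 2:]                                  # (k, k-2)
    rotation = U @ Z                              # (n_knots, k-2)
    S_pen = Z.T @ (D[:, None] * Z)                # Z' D Z, PSD on the range

    rx = np.abs(xs[:, None] - knots[None, :])
    cols = (rx ** 3) @ rotation
    design = np.column_stack([cols, xs])

    col_scale = np.sqrt(np.mean(design ** 2, axis=0))
    col_scale[col_scale == 0] = 1.0
    design = design / col_scale

    # penalty in the rescaled coordinates (linear column unpenalized)
    S = np.zeros((design.shape[1], design.shape[1]))
    Cs = np.diag(col_scale[:-1])
    S[:-1, :-1] = Cs @ S_pen @ Cs
    fro = np.linalg.norm(S)
    if fro > 0:
        S /= fro

    col_mean = design.mean(axis=0)
    design = design - col_mean

    basis = SmoothBasis(
        knots=knots, rotation=rotation, x_shift=lo, x_scale=hi - lo,
        col_scale=col_scale, col_mean=col_mean, penalty=S, k=k,
    )
    return design, basis


# ---------------------------------------------------------------------------
# binomial deviance and PIRLS
# ---------------------------------------------------------------------------


def binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Binomial deviance for proportions y with prior weights (trial counts)."""
    y = np.asarray(y, float)
    mu = np.clip(np.asarray(mu, float), _EPS_MU, 1 - _EPS_MU)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _pirls(X: np.ndarray, y: np.ndarray, w: np.ndarray, S_total: np.ndarray,
           beta0: np.ndarray | None = None, max_iter: int = 100,
           tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Penalized IRLS for a binomial GLM with logit link.

    Returns (beta, XtWX at convergence, deviance, n_iter, converged).
    """
    n, p = X.shape
    if beta0 is None:
        # standard GLM starting values: shrink proportions off the boundary
        mu = (w * y + 0.5) / (w + 1.0)
        eta = np.log(mu / (1 - mu))
        beta = None
    else:
        beta = beta0.copy()
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))

    dev = binomial_deviance(y, mu, w)
    converged = False
    it = 0
    XtWX = None
    for it in range(1, max_iter + 1):
        mu = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
        var = mu * (1 - mu)
        z = eta + (y - mu) / var
        W = w * var
        XtWX = (X * W[:, None]).T @ X
        XtWz = (X * W[:, None]).T @ z
        # small ridge keeps rank-deficient designs (few distinct covariate
        # vectors, e.g. one soil profile per site-year) numerically solvable
        ridge = 1e-9 * (np.trace(XtWX) / p) * np.eye(p)
        H = XtWX + S_total + ridge
        try:
            c, low = cho_factor(H, lower=True)
            beta_new = cho_solve((c, low), XtWz)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H, XtWz, rcond=None)[0]
        eta_new = X @ beta_new
        mu_new = 1.0 / (1.0 + np.exp(-eta_new))
        dev_new = binomial_deviance(y, mu_new, w)
        # step-halving if the penalized objective worsens badly
        step = 1.0
        pen_old = dev + (beta @ S_total @ beta if beta is not None else 0.0)
        while np.isnan(dev_new) or (
            beta is not None
            and dev_new + beta_new @ S_total @ beta_new > pen_old + 1e-6 * abs(pen_old)
            and step > 1e-4
        ):
            step /= 2.0
            beta_new = step * beta_new + (1 - step) * (beta if beta is not None else 0.0)
            eta_new = X @ beta_new
            mu_new = 1.0 / (1.0 + np.exp(-eta_new))
            dev_new = binomial_deviance(y, mu_new, w)
        rel = abs(dev - dev_new) / (abs(dev_new) + 0.1)
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        if rel < tol:
            converged = True
            break
    # recompute XtWX at the converged coefficients for edf / covariance
    var = np.clip(mu, _EPS_MU, 1 - _EPS_MU) * (1 - np.clip(mu, _EPS_MU, 1 - _EPS_MU))
    XtWX = (X * (w * var)[:, None]).T @ X
    return beta, XtWX, dev, it, converged


@dataclass
class PenalizedFit:
    """Result of a penalized binomial GLM fit.

    ``covariance`` is the Bayesian posterior covariance
    ``phi * (X'WX + S_lambda)^-1``; ``phi`` is 1 for the binomial family and
    the Pearson estimate for quasibinomial. ``lambdas`` holds the selected
    smoothing parameter for each penalty block, in block order.
    """

    beta: np.ndarray
    covariance: np.ndarray
    lambdas: np.ndarray
    edf: float
    deviance: float
    phi: float
    gcv: float
    n_obs: int
    n_iter: int
    converged: bool

    @property
    def lam(self) -> float:
        """Geometric-mean smoothing parameter (summary diagnostic)."""
        return float(np.exp(np.mean(np.log(self.lambdas)))) if len(self.lambdas) else 0.0


def _assemble_S(p: int, blocks, lambdas) -> np.ndarray:
    S = np.zeros((p, p))
    for (sl, S_j), lam in zip(blocks, lambdas):
        S[sl, sl] += lam * S_j
    return S


def _working_gcv(A: np.ndarray, Xtz: np.ndarray, ztz: float, n: int,
                 S_total: np.ndarray, ridge: np.ndarray,
                 gamma: float = 2.0) -> tuple[float, float]:
    """GCV of the penalized weighted-least-squares working problem.

    A = X'WX, Xtz = X'Wz, ztz = z'Wz are fixed; returns (gcv, edf). The
    ``gamma`` factor inflates the effective-degrees-of-freedom cost — the
    standard guard against GCV's tendency to undersmooth.
    """
    H = A + S_total + ridge
    try:
        c, low = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    beta = cho_solve((c, low), Xtz)
    # ||sqrt(W)(z - Xb)||^2 = z'Wz - 2 b'X'Wz + b'A b
    rss = ztz - 2 * beta @ Xtz + beta @ A @ beta
    edf = float(np.trace(cho_solve((c, low), A)))
    denom = max(n - gamma * edf, 1e-6)
    return float(n * rss / denom ** 2), edf


def fit_penalized_glm(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      penalty_blocks, family: str = "quasibinomial",
                      lam_grid: np.ndarray | None = None,
                      n_outer: int = 2, gamma: float = 2.0) -> PenalizedFit:
    """Fit a binomial GAM with per-term smoothing parameters.

    Smoothing selection follows the performance-iteration scheme: PIRLS is
    run to convergence at the current smoothing parameters, the working
    weights and response are frozen, and the per-block lambdas are updated
    by GCV on the resulting weighted-least-squares problem — first a shared
    grid search, then cyclic per-block refinement on a multiplicative grid —
    after which PIRLS is re-run. Two outer cycles suffice in practice.
    GCV is invariant to the dispersion scale, so the same criterion serves
    binomial and quasibinomial fits.

    Parameters
    ----------
    X:
        Full model matrix (intercept, factor dummies, smooth columns).
    y, w:
        Response proportions and prior weights (trial counts).
    penalty_blocks:
        List of ``(slice, S_block)`` pairs, one per smooth term block; each
        block is Frobenius-normalized so lambdas are comparable.
    family:
        ``"binomial"`` (dispersion fixed at 1) or ``"quasibinomial"``
        (Pearson dispersion estimate; the default, since tiller counts are
        overdispersed relative to nominal binomial variance at 300000
        trials).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n, p = X.shape
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family {family!r}")
    if lam_grid is None:
        lam_grid = np.logspace(-6, 8, 15)
    blocks = list(penalty_blocks)
    n_blocks = len(blocks)

    lambdas = np.ones(n_blocks)
    beta = None
    gcv = np.nan

    if n_blocks == 0:
        beta, XtWX, dev, n_iter, conv = _pirls(X, y, w, np.zeros((p, p)))
        S_total = np.zeros((p, p))
    else:
        for outer in range(n_outer):
            S_total = _assemble_S(p, blocks, lambdas)
            beta, XtWX, dev, n_iter, conv = _pirls(X, y, w, S_total, beta0=beta)
            # freeze the working problem at the current fit
            eta = X @ beta
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _EPS_MU, 1 - _EPS_MU)
            var = mu * (1 - mu)
            z = eta + (y - mu) / var
            W = w * var
            A = (X * W[:, None]).T @ X
            Xtz = (X * W[:, None]).T @ z
            ztz = float(np.sum(W * z * z))
            ridge = 1e-9 * (np.trace(A) / p) * np.eye(p)

            if outer == 0:
                # put each penalty on the curvature scale of its design
                # block, so the dimensionless lambda grid can reach both the
                # unpenalized and the fully-smoothed limit regardless of the
                # (very large) binomial weights
                blocks = [
                    (sl, S_j * (np.trace(A[sl, sl]) / max(np.trace(S_j), 1e-300)))
                    for sl, S_j in blocks
                ]
                # shared grid search seeds the per-block refinement
                best_lam, best_gcv = lambdas.copy(), np.inf
                for lam in lam_grid:
                    cand = np.full(n_blocks, lam)
                    g, _ = _working_gcv(A, Xtz, ztz, n, _assemble_S(p, blocks, cand), ridge, gamma)
                    if g < best_gcv:
                        best_gcv, best_lam = g, cand
                lambdas = best_lam
            # cyclic per-block refinement
            gcv, _ = _working_gcv(A, Xtz, ztz, n, _assemble_S(p, blocks, lambdas), ridge, gamma)
            for _sweep in range(2):
                improved = False
                for j in range(n_blocks):
                    for factor in (0.01, 0.1, 10.0, 100.0):
                        cand = lambdas.copy()
                        cand[j] = np.clip(cand[j] * factor, 1e-8, 1e12)
                        g, _ = _working_gcv(A, Xtz, ztz, n,
                                            _assemble_S(p, blocks, cand), ridge, gamma)
                        if g < gcv - 1e-12:
                            gcv, lambdas, improved = g, cand, True
                if not improved:
                    break
        # final fit at the selected smoothing parameters
        S_total = _assemble_S(p, blocks, lambdas)
        beta, XtWX, dev, n_iter, conv = _pirls(X, y, w, S_total, beta0=beta)

    if not conv:
        raise RuntimeError(f"PIRLS did not converge in {n_iter} iterations")

    ridge = 1e-9 * (np.trace(XtWX) / p) * np.eye(p)
    H = XtWX + S_total + ridge
    try:
        c, low = cho_factor(H, lower=True)
        edf = float(np.trace(cho_solve((c, low), XtWX)))
    except np.linalg.LinAlgError:
        edf = float(np.trace(np.linalg.pinv(H) @ XtWX))
    if not np.isfinite(gcv):
        gcv = n * dev / max(n - edf, 1e-6) ** 2

    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), _EPS_MU, 1 - _EPS_MU)
    pearson = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))
    phi = 1.0 if family == "binomial" else max(pearson / max(n - edf, 1.0), 1e-12)

    try:
        cov = phi * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = phi * np.linalg.pinv(H)

    return PenalizedFit(
        beta=beta, covariance=cov, lambdas=lambdas, edf=edf, deviance=dev,
        phi=phi, gcv=float(gcv), n_obs=n, n_iter=n_iter, converged=conv,
    )
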