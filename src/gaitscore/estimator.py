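"""Fitting the bounded parallel-hyperplane scorer.

The loss balances per-level mean absolute error against an L2 penalty on
the scale-weighted coefficients and a barrier keeping the demarcation
hyperplanes apart:

``L = (sum_j E_j) / N  +  lambda * R1  +  beta * R2``

* ``E_j`` — mean |y_i - Y_i| over training rows with clinician level j,
  using the continuous score y (not rounded); the sum runs over the N
  levels actually present in the training set.
* ``R1 = sum_k (w_k * std(x_k))^2`` — ridge penalty weighted by the raw
  per-feature training standard deviations (n-1 denominator), which makes
  the regularisation invariant to feature units.
* ``R2 = 1/(bu-p4) + 1/(p4-p3) + 1/(p3-p2) + 1/(p2-p1) + 1/(p1-bl)`` —
  reciprocal-gap barrier (equals 5.0 at the default, evenly spaced, p).

Optimisation is sequential quadratic programming (SLSQP) with numerical
gradients from a single deterministic start (w = 0, c = 0,
p = (0.5, 1.5, 2.5, 3.5)), under the feasibility constraints
``p1 >= bl``, ``p_{i+1} - p_i >= eps_gap``, ``p4 <= bu``.  The absolute
value in E_j is kept non-smooth by default; a Huber smoothing is available
behind ``huber_delta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, InsufficientDataError, ModelError
from .model import (
    DEFAULT_P,
    SCORE_LOWER,
    SCORE_UPPER,
    ScorerParams,
    round_to_level,
    validate_params,
)

_BIG = 1e12  # penalty returned for infeasible line-search iterates


@dataclass
class LossBreakdown:
    """The loss and its components at a parameter point."""

    e_levels: dict  #: level -> mean absolute error E_j
    r1: float
    r2: float
    total: float
    n_levels: int
    std_x: np.ndarray

    @property
    def error_term(self) -> float:
        return sum(self.e_levels.values()) / self.n_levels


def _score_fast(X, w, c, p, bl, bu):
    """Unchecked score chain for use inside the optimiser hot loop."""
    xhp = np.clip(X @ w + c, -500.0, 500.0)  # avoid exp overflow at extremes
    yrd = (bu - bl) / (1.0 + np.exp(-(xhp - 0.5 * (bu + bl)))) + bl
    bounds = np.concatenate(([bl], p, [bu]))
    j = np.clip(np.searchsorted(bounds, yrd, side="left") - 1, 0, 4)
    return (yrd - bounds[j]) / (bounds[j + 1] - bounds[j]) + bl + j


def loss(params: ScorerParams, X, y, lambda_: float = 0.1, beta: float = 0.005,
         std_x: np.ndarray | None = None,
         huber_delta: float | None = None) -> LossBreakdown:
    """Evaluate the training loss of *params* on a labelled dataset.

    ``std_x`` defaults to the per-feature sample standard deviation of *X*
    itself; pass the training-fold value when evaluating on other data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise InsufficientDataError("empty dataset")
    if std_x is None:
        std_x = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    gaps = np.diff(np.concatenate(([params.bl], params.p, [params.bu])))
    if np.any(gaps <= 0):
        raise ModelError("zero or negative hyperplane gap: R2 is infinite")
    scores = _score_fast(X, params.w, params.c, params.p, params.bl, params.bu)
    abs_err = np.abs(scores - y)
    if huber_delta:
        d = huber_delta
        abs_err = np.where(abs_err <= d, 0.5 * abs_err**2 / d, abs_err - 0.5 * d)
    levels = np.unique(y)
    e_levels = {int(l): float(abs_err[y == l].mean()) for l in levels}
    r1 = float(np.sum((params.w * std_x) ** 2))
    r2 = float(np.sum(1.0 / gaps))
    total = sum(e_levels.values()) / len(levels) + lambda_ * r1 + beta * r2
    return LossBreakdown(
        e_levels=e_levels, r1=r1, r2=r2, total=float(total),
        n_levels=len(levels), std_x=np.asarray(std_x, dtype=float),
    )


def make_objective(X, y, lambda_: float = 0.1, beta: float = 0.005,
                   huber_delta: float | None = None):
    """Build ``(objective, gradient)`` closures over theta = [w, c, p1..p4].

    The gradient is the analytic (sub)gradient of the loss; at the kinks of
    the absolute error it returns the sign-convention subgradient.  Exposed
    for testability; :meth:`HyperplaneGaitScorer.fit` consumes it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    bl, bu = SCORE_LOWER, SCORE_UPPER
    std_x = X.std(axis=0, ddof=1) if n > 1 else np.zeros(m)
    levels = np.unique(y)
    n_levels = len(levels)
    masks = [y == l for l in levels]
    row_w = np.zeros(n)
    for mk in masks:
        row_w[mk] = 1.0 / (mk.sum() * n_levels)
    lam, delta = lambda_, huber_delta

    def objective(theta):
        w, c, p = theta[:m], theta[m], theta[m + 1:]
        gaps = np.diff(np.concatenate(([bl], p, [bu])))
        if np.any(gaps <= 0):
            return _BIG * (1.0 + float(np.sum(np.maximum(-gaps, 0.0))))
        scores = _score_fast(X, w, c, p, bl, bu)
        abs_err = np.abs(scores - y)
        if delta:
            abs_err = np.where(abs_err <= delta,
                               0.5 * abs_err**2 / delta, abs_err - 0.5 * delta)
        err = float(np.sum(row_w * abs_err))
        r1 = np.sum((w * std_x) ** 2)
        r2 = np.sum(1.0 / gaps)
        return err + lam * r1 + beta * r2

    def gradient(theta):
        w, c, p = theta[:m], theta[m], theta[m + 1:]
        bounds = np.concatenate(([bl], p, [bu]))
        gaps = np.diff(bounds)
        if np.any(gaps <= 0):
            g = np.zeros(m + 5)
            g[m + 1:] = -np.sign(np.concatenate(([1], np.diff(p))))
            return g * _BIG
        xhp = np.clip(X @ w + c, -500.0, 500.0)
        s = 1.0 / (1.0 + np.exp(-(xhp - 0.5 * (bu + bl))))
        yrd = (bu - bl) * s + bl
        j = np.clip(np.searchsorted(bounds, yrd, side="left") - 1, 0, 4)
        gj = gaps[j]
        scores = (yrd - bounds[j]) / gj + bl + j
        resid = scores - y
        if delta:
            dabs = np.where(np.abs(resid) <= delta, resid / delta, np.sign(resid))
        else:
            dabs = np.sign(resid)
        rho = row_w * dabs
        dy_dxhp = (bu - bl) * s * (1.0 - s) / gj
        gw = X.T @ (rho * dy_dxhp) + 2.0 * lam * w * std_x**2
        gc = float(np.sum(rho * dy_dxhp))
        gp = np.zeros(4)
        d_lower = rho * (yrd - bounds[j + 1]) / gj**2  # d score / d lower bound
        d_upper = -rho * (yrd - bounds[j]) / gj**2  # d score / d upper bound
        for k in range(1, 5):  # p_k is bounds[k]
            gp[k - 1] = d_lower[j == k].sum() + d_upper[j == k - 1].sum()
        gp += beta * (-1.0 / gaps[:4] ** 2 + 1.0 / gaps[1:] ** 2)
        return np.concatenate([gw, [gc], gp])

    return objective, gradient, std_x


class HyperplaneGaitScorer(BaseEstimator):
    """Continuous UPDRS gait-task scorer with four trained parallel hyperplanes.

    Parameters
    ----------
    lambda_ : float, default 0.1
        Weight of the ridge term R1.
    beta : float, default 0.005
        Weight of the hyperplane-gap barrier R2.
    eps_gap : float, default 1e-3
        Minimal numerical gap enforced between consecutive demarcation
        values (the model's strict inequalities need a closed feasible set).
    huber_delta : float or None, default None
        If set, smooth the absolute error with a Huber transition of this
        width.
    max_iter : int, default 300
    tol : float, default 1e-10
        SLSQP convergence tolerance.

    Attributes
    ----------
    coef_ : ndarray, (n_features,) — fitted w.
    intercept_ : float — fitted c.
    thresholds_ : ndarray, (4,) — fitted demarcation values p1..p4.
    params_ : ScorerParams — the full parameter bundle.
    loss_breakdown_ : LossBreakdown at the optimum.
    """

    def __init__(self, lambda_: float = 0.1, beta: float = 0.005,
                 eps_gap: float = 1e-3, huber_delta: float | None = None,
                 max_iter: int = 300, tol: float = 1e-10,
                 jac: str = "analytic", feature_names: list | None = None):
        self.lambda_ = lambda_
        self.beta = beta
        self.eps_gap = eps_gap
        self.huber_delta = huber_delta
        self.max_iter = max_iter
        self.tol = tol
        self.jac = jac
        self.feature_names = feature_names

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Fit on features *X* (n, m) and clinician levels *y* (integers 0..4)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ModelError("X must be 2-dimensional")
        n, m = X.shape
        if n < 2 or np.unique(y).size < 2:
            raise InsufficientDataError("need at least 2 rows spanning >= 2 levels")
        bl, bu = SCORE_LOWER, SCORE_UPPER
        lam, beta, delta = self.lambda_, self.beta, self.huber_delta
        objective, gradient, std_x = make_objective(X, y, lam, beta, delta)

        theta0 = np.concatenate([np.zeros(m), [0.0], DEFAULT_P])
        if objective(theta0) >= _BIG:
            raise FitError("infeasible initial parameters")

        eg = self.eps_gap
        constraints = [
            {"type": "ineq", "fun": lambda th: th[m + 1] - bl},
            {"type": "ineq", "fun": lambda th: th[m + 2] - th[m + 1] - eg},
            {"type": "ineq", "fun": lambda th: th[m + 3] - th[m + 2] - eg},
            {"type": "ineq", "fun": lambda th: th[m + 4] - th[m + 3] - eg},
            {"type": "ineq", "fun": lambda th: bu - th[m + 4]},
        ]
        jac = gradient if self.jac == "analytic" else None
        res = minimize(objective, theta0, method="SLSQP", jac=jac,
                       constraints=constraints,
                       options={"maxiter": self.max_iter, "ftol": self.tol})
        theta = res.x if np.isfinite(res.fun) and res.fun <= objective(theta0) else theta0
        w, c, p = theta[:m], float(theta[m]), np.sort(theta[m + 1:])
        p = np.clip(p, bl, bu)
        names = list(self.feature_names) if self.feature_names else []
        params = ScorerParams(w=w, c=c, p=p, features=names)
        try:
            validate_params(params)
        except ModelError as exc:
            raise FitError(f"optimiser left the feasible set: {exc}",
                           last_params=params) from exc
        self.params_ = params
        self.coef_ = params.w
        self.intercept_ = params.c
        self.thresholds_ = params.p
        self.n_features_in_ = m
        self.loss_breakdown_ = loss(params, X, y, lam, beta,
                                    std_x=std_x, huber_delta=delta)
        self.n_iter_ = int(res.nit)
        return self

    # -- prediction --------------------------------------------------------

    def decision_function(self, X):
        """Signed hyperplane distance xhp of each row."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_score(self, X):
        """Continuous severity score in (-0.5, 4.5)."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        p = self.params_
        return _score_fast(X, p.w, p.c, p.p, p.bl, p.bu)

    def predict(self, X):
        """Rounded integer level in {0..4}."""
        return round_to_level(self.predict_score(X))
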