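"""Bounded parallel-hyperplane scoring model.

The model maps a gait feature vector ``x`` to a continuous severity score
``y`` on the UPDRS gait-task scale.  Four parallel hyperplanes in feature
space separate the five ordinal levels; the score is obtained in three
strictly increasing stages:

1. ``xhp = w . x + c`` — signed distance of the point to the hyperplane
   family (``w`` absorbs the usual ``1/||W||`` normalisation, so the pair
   ``(w, c)`` is the trained parameterisation and the un-normalised
   ``(W, C, D_i)`` form is never materialised).
2. ``yrd = (bu - bl) / (1 + exp(-(xhp - (bu + bl)/2))) + bl`` — a sigmoid
   bounding the distance to the open interval ``(bl, bu) = (-0.5, 4.5)``,
   the valid range of a rounded five-level score.
3. A continuous piecewise-linear map sending the four demarcation values
   ``p1 < p2 < p3 < p4`` of ``yrd`` to 0.5, 1.5, 2.5 and 3.5, so that each
   unit score interval ``l +/- 0.5`` corresponds to one ordinal level even
   when the levels are unevenly spaced in feature space.

All functions here are pure and vectorised over the leading axis; fitting
lives in :mod:`gaitscore.estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError

#: Lower / upper bound of the continuous score.
SCORE_LOWER = -0.5
SCORE_UPPER = 4.5

#: Default demarcation values: evenly spaced levels.
DEFAULT_P = (0.5, 1.5, 2.5, 3.5)


@dataclass
class ScorerParams:
    """Trained parameters of the nonlinear scorer.

    Attributes
    ----------
    w : ndarray, shape (n_features,)
        Hyperplane coefficient vector (pre-normalised direction).
    c : float
        Scalar offset.
    p : ndarray, shape (4,)
        Demarcation values of the bounded distance ``yrd`` at the four
        level-separating hyperplanes; must satisfy
        ``bl <= p1 < p2 < p3 < p4 <= bu``.
    features : list of str
        Ordered names of the model inputs (defines the layout of ``w``).
    """

    w: np.ndarray
    c: float
    p: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_P))
    features: list[str] = field(default_factory=list)
    bl: float = SCORE_LOWER
    bu: float = SCORE_UPPER

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.c = float(self.c)
        if self.p.shape != (4,):
            raise ModelError(f"p must have four entries, got shape {self.p.shape}")


def check_constraints(params: ScorerParams) -> list[str]:
    """Return the list of violated model constraints (empty means feasible).

    The constraint set keeps every level segment non-degenerate:
    ``p1 - bl >= 0``, ``p(i+1) - p(i) > 0`` for i = 1..3, ``bu - p4 >= 0``.
    """
    p, bl, bu = params.p, params.bl, params.bu
    violations = []
    if p[0] - bl < 0:
        violations.append(f"p1 - bl >= 0 violated: p1 = {p[0]:g} < bl = {bl:g}")
    for i in range(3):
        if p[i + 1] - p[i] <= 0:
            violations.append(
                f"p{i + 2} - p{i + 1} > 0 violated: p{i + 2} = {p[i + 1]:g}, "
                f"p{i + 1} = {p[i]:g}"
            )
    if bu - p[3] < 0:
        violations.append(f"bu - p4 >= 0 violated: p4 = {p[3]:g} > bu = {bu:g}")
    return violations


def validate_params(params: ScorerParams) -> ScorerParams:
    """Raise :class:`ModelError` if *params* violate the constraint set."""
    violations = check_constraints(params)
    if violations:
        raise ModelError("; ".join(violations))
    return params


def signed_distance(x, params: ScorerParams):
    """Signed distance ``xhp = w . x + c`` of point(s) *x* to the hyperplane family.

    *x* may be a single vector or an ``(n, n_features)`` array.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.w.shape[0]:
        raise ModelError(
            f"feature dimension mismatch: x has {x.shape[-1]}, model expects "
            f"{params.w.shape[0]}"
        )
    return x @ params.w + params.c


def bounded_distance(xhp, bl: float = SCORE_LOWER, bu: float = SCORE_UPPER):
    """Sigmoid-bounded distance ``yrd`` in the open interval ``(bl, bu)``.

    ``yrd = (bu - bl) / (1 + exp(-(xhp - (bu + bl)/2))) + bl``; with the
    default bounds this is ``5 / (1 + exp(-xhp + 2)) - 0.5``.  Strictly
    increasing in ``xhp``.
    """
    xhp = np.asarray(xhp, dtype=float)
    mid = 0.5 * (bu + bl)
    expo = np.clip(-(xhp - mid), None, 700.0)  # exp overflow guard
    out = (bu - bl) / (1.0 + np.exp(expo)) + bl
    return out if out.ndim else float(out)


def inverse_bounded_distance(yrd, bl: float = SCORE_LOWER, bu: float = SCORE_UPPER):
    """Inverse of :func:`bounded_distance`: the ``xhp`` producing a given ``yrd``."""
    yrd = np.asarray(yrd, dtype=float)
    mid = 0.5 * (bu + bl)
    out = mid - np.log((bu - bl) / (yrd - bl) - 1.0)
    return out if out.ndim else float(out)


def piecewise_score(yrd, params: ScorerParams):
    """Continuous piecewise-linear score ``y`` from the bounded distance ``yrd``.

    With segment boundaries ``(bl, p1, p2, p3, p4, bu)``, a value in segment
    ``j`` (0-based level index) maps to
    ``y = (yrd - lower_j) / (upper_j - lower_j) + bl + j``,
    which is continuous, strictly increasing, and sends each demarcation
    value ``p_i`` to ``i - 0.5``.
    """
    validate_params(params)
    yrd = np.asarray(yrd, dtype=float)
    bl, bu = params.bl, params.bu
    if np.any(yrd <= bl) or np.any(yrd >= bu):
        raise ModelError(f"yrd must lie strictly inside ({bl:g}, {bu:g})")
    bounds = np.concatenate(([bl], params.p, [bu]))
    # segment index j such that bounds[j] < yrd <= bounds[j+1] (top segment open)
    j = np.clip(np.searchsorted(bounds, yrd, side="left") - 1, 0, 4)
    lower = bounds[j]
    upper = bounds[j + 1]
    y = (yrd - lower) / (upper - lower) + bl + j
    return y if y.ndim else float(y)


def score(x, params: ScorerParams):
    """Continuous severity score of feature vector(s) *x*: Eqs. of the model chained.

    Composition ``piecewise_score(bounded_distance(signed_distance(x)))``;
    strictly increasing in the signed distance and confined to
    ``(bl, bu) = (-0.5, 4.5)``.
    """
    yrd = bounded_distance(signed_distance(x, params), params.bl, params.bu)
    # float saturation at extreme xhp can land exactly on a bound that the
    # exact sigmoid never attains; nudge back into the open interval
    eps = 1e-12
    yrd = np.clip(yrd, params.bl + eps, params.bu - eps)
    return piecewise_score(yrd, params)


def round_to_level(y):
    """Round continuous score(s) to the nearest integer level in {0..4}.

    Exact half-points round up (toward higher severity): 2.5 -> 3.
    """
    y = np.asarray(y, dtype=float)
    level = np.clip(np.floor(y + 0.5), 0, 4).astype(int)
    return level if level.ndim else int(level)


def hyperplane_positions(params: ScorerParams):
    """The ``xhp`` locations of the four demarcation hyperplanes.

    These are the signed distances at which the rounded level changes;
    obtained by pulling the demarcation values ``p_i`` back through the
    sigmoid.
    """
    return inverse_bounded_distance(params.p, params.bl, params.bu)
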