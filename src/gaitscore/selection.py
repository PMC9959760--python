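"""Feature screening and greedy wrapper selection.

A one-way ANOVA across the clinician levels (healthy subjects counted as
level 0) first removes features whose distributions do not differ between
levels (p >= 0.01 by default).  A greedy forward search then grows the
feature set one feature at a time, at each step adding the single feature
that most decreases (or least increases) the LOSO mean estimation error,
and records the whole error-vs-set-size curve; the optimal set is the
curve's minimiser (ties broken toward the smaller set, then canonical
feature order).  A backward-elimination mode is available for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .errors import InsufficientDataError
from .evaluation import estimation_errors, loso_cv
from .io import FEATURE_NAMES


def anova_filter(table: pd.DataFrame, alpha: float = 0.01,
                 features: list | None = None):
    """One-way fixed-effects ANOVA per feature across level groups.

    Returns ``(retained_names, pvalues)`` where retained features have
    p < *alpha*.  A feature identical in every group gets F = 0, p = 1.
    """
    cols = features or [c for c in FEATURE_NAMES if c in table.columns]
    levels = table["rated_level"]
    groups = [table.loc[levels == l] for l in sorted(levels.unique())]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("ANOVA needs >= 2 groups with >= 2 rows each")
    for g in groups:
        if (g[cols].std(ddof=1) == 0).all():
            raise InsufficientDataError(
                "a level group has zero variance in every feature"
            )
    pvals = {}
    for col in cols:
        samples = [g[col].to_numpy(float) for g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            pvals[col] = 1.0  # identical everywhere: F = 0
            continue
        with np.errstate(invalid="ignore"):
            stat = f_oneway(*samples)
        pvals[col] = 1.0 if np.isnan(stat.pvalue) else float(stat.pvalue)
    pvalues = pd.Series(pvals, name="pvalue")
    retained = [c for c in cols if pvalues[c] < alpha]
    return retained, pvalues


def _loso_mean_error(table, feats, model, standardize, model_kwargs):
    res = loso_cv(table, features=list(feats), model=model,
                  standardize=standardize, **model_kwargs)
    _, mean_e = estimation_errors(res["pred_level"], res["true_level"])
    return mean_e


def greedy_search(table: pd.DataFrame, model: str = "nonlinear",
                  features: list | None = None, direction: str = "forward",
                  standardize: str = "auto", **model_kwargs) -> dict:
    """Greedy wrapper feature search driven by LOSO mean estimation error.

    Returns ``{"model", "curve": [{"k", "features", "mean_error"}, ...],
    "optimal": {"features", "mean_error"}}``.  The forward mode starts
    empty and adds; ``direction='backward'`` starts full and removes.
    Deterministic: ties are resolved by canonical feature order.
    """
    pool = list(features or [c for c in FEATURE_NAMES if c in table.columns])
    if not pool:
        raise InsufficientDataError("empty candidate feature set")
    order = {name: i for i, name in enumerate(pool)}
    curve = []

    if direction == "forward":
        selected: list = []
        remaining = list(pool)
        while remaining:
            best = None
            for cand in sorted(remaining, key=order.get):
                err = _loso_mean_error(table, selected + [cand], model,
                                       standardize, model_kwargs)
                if best is None or err < best[0]:
                    best = (err, cand)
            selected.append(best[1])
            remaining.remove(best[1])
            curve.append({"k": len(selected), "features": list(selected),
                          "mean_error": best[0]})
    elif direction == "backward":
        selected = list(pool)
        err = _loso_mean_error(table, selected, model, standardize, model_kwargs)
        curve.append({"k": len(selected), "features": list(selected),
                      "mean_error": err})
        while len(selected) > 1:
            best = None
            for cand in sorted(selected, key=order.get):
                trial = [f for f in selected if f != cand]
                err = _loso_mean_error(table, trial, model, standardize, model_kwargs)
                if best is None or err < best[0]:
                    best = (err, cand)
            selected.remove(best[1])
            curve.append({"k": len(selected), "features": list(selected),
                          "mean_error": best[0]})
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")

    # optimal: minimum error, ties toward smaller set then recording order
    best_entry = min(curve, key=lambda c: (c["mean_error"], c["k"]))
    return {
        "model": model,
        "curve": curve,
        "optimal": {"features": list(best_entry["features"]),
                    "mean_error": best_entry["mean_error"]},
    }
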