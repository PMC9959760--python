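"""Leave-one-subject-out cross-validation and error statistics.

Every reported error follows the same recipe: the continuous score (or
class prediction) of each held-out subject is rounded to a level, the
estimation error is ``e = |rounded score - clinician level|``, and its
cumulative distribution ``c_i = 100 * #{e <= i} / N_T`` summarises how
often the model is exactly right (c_0) or within one level (c_1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import MODEL_KINDS, make_model
from .errors import InsufficientDataError
from .features import HealthyReferenceScaler
from .io import FEATURE_NAMES


def estimation_errors(pred_levels, true_levels):
    """Per-subject absolute level errors and their mean."""
    pred = np.asarray(pred_levels, dtype=float)
    true = np.asarray(true_levels, dtype=float)
    e = np.abs(pred - true)
    return e, float(e.mean())


def cumulative_distribution(e) -> np.ndarray:
    """Cumulative error distribution in percent: entry i is 100 * P(e <= i).

    The array extends to the largest observed error, so its last entry is
    always 100.
    """
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise InsufficientDataError("empty error vector: distribution undefined")
    top = int(np.ceil(e.max()))
    return np.array([100.0 * np.mean(e <= i) for i in range(top + 1)])


def per_group_error_counts(report: pd.DataFrame,
                           groups: pd.Series | None = None) -> pd.Series:
    """Number of mis-scored subjects (e > 0) per participant group.

    Groups default to "healthy" for healthy subjects and "pd_level<j>" for
    patients, mirroring the healthy / PD-level breakdown of the results.
    """
    if groups is None:
        if "group" not in report.columns:
            raise InsufficientDataError("no groups given and no 'group' column")
        groups = np.where(report["group"] == "healthy", "healthy",
                          "pd_level" + report["true_level"].astype(int).astype(str))
        groups = pd.Series(groups, index=report.index)
    wrong = report["pred_level"] != report["true_level"]
    return wrong.groupby(groups.loc[report.index]).sum().astype(int)


@dataclass
class EvalReport:
    """LOSO evaluation summary for one model."""

    model: str
    per_subject: pd.DataFrame  #: columns true_level, score, pred_level
    mean_error: float
    cumulative: np.ndarray
    group_counts: pd.Series | None = None

    @property
    def exact_accuracy(self) -> float:
        return self.cumulative[0] / 100.0

    @property
    def within_one_accuracy(self) -> float:
        return self.cumulative[1] / 100.0 if len(self.cumulative) > 1 else 1.0


def _fold_scaler(train: pd.DataFrame, cols, mode: str):
    if mode is None or mode == "none":
        return None
    ref = train
    if mode in ("auto", "healthy") and "group" in train.columns:
        healthy = train[train["group"] == "healthy"]
        if len(healthy) >= 2:
            ref = healthy
        elif mode == "healthy":
            raise InsufficientDataError("fewer than 2 healthy rows for standardization")
    return HealthyReferenceScaler(on_zero_std="unit").fit(ref[cols].to_numpy(float))


def loso_cv(table: pd.DataFrame, features: list | None = None,
            model: str = "nonlinear", standardize: str = "auto",
            **model_kwargs) -> pd.DataFrame:
    """Leave-one-subject-out predictions for one model.

    *table* is indexed by subject_id with feature columns plus
    ``rated_level`` (and optionally ``group``).  Per fold, the feature
    scaler and the scorer are re-fitted on the training subjects only
    (``standardize='auto'``: z-score by the fold's healthy rows when at
    least two exist, else by all training rows; ``'none'``: raw features).
    Returns a frame with columns ``true_level, score, pred_level``.
    """
    cols = features or [c for c in FEATURE_NAMES if c in table.columns]
    if table.shape[0] < 3:
        raise InsufficientDataError("LOSO needs at least 3 subjects")
    rows = {}
    for subject in table.index:
        train = table.drop(index=subject)
        test = table.loc[[subject]]
        if train["rated_level"].nunique() < 2:
            warnings.warn(f"fold {subject}: training set has a single level; skipped",
                          stacklevel=2)
            continue
        scaler = _fold_scaler(train, cols, standardize)
        Xtr = train[cols].to_numpy(float)
        Xte = test[cols].to_numpy(float)
        if scaler is not None:
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        est = make_model(model, **model_kwargs)
        est.fit(Xtr, train["rated_level"].to_numpy())
        if hasattr(est, "predict_score"):
            score = float(np.atleast_1d(est.predict_score(Xte))[0])
            pred = int(np.atleast_1d(est.predict(Xte))[0])
        else:  # classifiers: the class itself is the score
            pred = int(np.atleast_1d(est.predict(Xte))[0])
            score = float(pred)
        rows[subject] = {
            "true_level": int(test["rated_level"].iloc[0]),
            "score": score,
            "pred_level": pred,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


def evaluate_models(table: pd.DataFrame, models=MODEL_KINDS,
                    features: dict | list | None = None,
                    standardize: str = "auto", **model_kwargs) -> dict:
    """LOSO-evaluate several models on identical folds; returns name -> EvalReport.

    *features* may be one list shared by all models or a dict of per-model
    lists (each model's own optimal set).  Folds are the subjects in table
    order for every model, so comparisons are paired.
    """
    reports = {}
    for kind in models:
        cols = features.get(kind) if isinstance(features, dict) else features
        res = loso_cv(table, features=cols, model=kind,
                      standardize=standardize, **model_kwargs)
        e, mean_e = estimation_errors(res["pred_level"], res["true_level"])
        report = EvalReport(
            model=kind,
            per_subject=res,
            mean_error=mean_e,
            cumulative=cumulative_distribution(e),
        )
        if "group" in table.columns:
            merged = res.join(table["group"])
            report.group_counts = per_group_error_counts(merged)
        reports[kind] = report
    return reports
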