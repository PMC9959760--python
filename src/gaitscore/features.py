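"""The twelve gait parameters and per-subject aggregation.

Spatio-temporal: SL (height-normalised stride length), GD (cycle duration,
s), PSP (swing phase, % of GD).  Kinematic: MH (max ankle height), RL
(lateral displacement range), RSZ/RSY/RSX (shank rotation ranges, deg),
MPV/MVV (max progression / vertical ankle velocity), MSV (max swing-phase
mediolateral angular velocity, deg/s), MHD (progression displacement at
the MH instant).  SL, MH, RL, MPV, MVV and MHD are divided by the
subject's height, making them dimensionless (velocities: 1/s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FeatureError, InsufficientDataError
from .io import FEATURE_NAMES, ImuSeries
from .kinematics import CycleKinematics
from .segmentation import GaitCycle


def compute_cycle_features(kin: CycleKinematics, cycle: GaitCycle,
                           series: ImuSeries, height: float) -> dict:
    """All twelve gait parameters of one cycle, as a name -> value dict.

    ``height`` is the subject's body height in metres; the landing-point
    datum for SL/MHD is the ankle position at the cycle-start heel strike
    and heights are measured from the same instant.
    """
    if height <= 0:
        raise FeatureError(f"height must be positive, got {height}")
    if cycle.to <= cycle.start_hs or cycle.end_hs <= cycle.to:
        raise FeatureError("degenerate cycle: TO does not split the cycle")
    t = kin.time
    gd = float(t[-1] - t[0])
    if gd <= 0:
        raise FeatureError("non-positive cycle duration")
    i_to = kin.to_offset
    swing = slice(i_to, len(t))

    pos, vel = kin.pos_pvl, kin.vel_pvl
    stride = float(pos[-1, 0] - pos[0, 0])  # P displacement between landings
    i_mh = int(np.argmax(pos[:, 1]))

    gz = np.degrees(series.gyro[cycle.start_hs:cycle.end_hs + 1, 2])
    msv = float(np.max(np.abs(gz[swing])))

    rot_range = kin.rot_deg.max(axis=0) - kin.rot_deg.min(axis=0)

    return {
        "SL": abs(stride) / height,
        "GD": gd,
        "PSP": 100.0 * float(t[-1] - t[i_to]) / gd,
        "MH": float(pos[i_mh, 1]) / height,
        "RL": float(pos[:, 2].max() - pos[:, 2].min()) / height,
        "RSZ": float(rot_range[2]),
        "RSY": float(rot_range[1]),
        "RSX": float(rot_range[0]),
        "MPV": float(np.max(vel[:, 0])) / height,
        "MVV": float(np.max(vel[:, 1])) / height,
        "MSV": msv,
        "MHD": abs(float(pos[i_mh, 0] - pos[0, 0])) / height,
    }


def aggregate_subject(per_cycle: list[dict]) -> dict:
    """Arithmetic mean over all steady cycles (both legs, all trials) of one subject."""
    if not per_cycle:
        raise InsufficientDataError("no cycles to aggregate")
    df = pd.DataFrame(per_cycle)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FeatureError(f"cycle features missing {missing}")
    return df[FEATURE_NAMES].mean(axis=0).to_dict()


class HealthyReferenceScaler(BaseEstimator, TransformerMixin):
    """Z-score features against a healthy reference population.

    ``fit`` receives the reference (healthy) rows only; ``transform`` maps
    any rows to ``z = (x - mean_ref) / std_ref`` columnwise.  Standard
    deviations use the n-1 denominator.  With ``on_zero_std='unit'`` a
    degenerate (constant) reference column is centred but left unscaled
    instead of raising.
    """

    def __init__(self, on_zero_std: str = "error"):
        self.on_zero_std = on_zero_std

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise InsufficientDataError("need at least 2 reference rows")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        self.n_features_in_ = X.shape[1]
        if np.any(self.std_ == 0):
            if self.on_zero_std == "unit":
                self.std_ = np.where(self.std_ == 0, 1.0, self.std_)
            else:
                k = int(np.argmax(self.std_ == 0))
                raise FeatureError(f"zero reference std for feature column {k}")
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.std_


def standardize(table: pd.DataFrame, reference: pd.DataFrame | None = None,
                columns: list[str] | None = None) -> pd.DataFrame:
    """Standardise a feature table by its healthy rows (or an explicit reference).

    By default the reference is ``table[table.group == 'healthy']``.  Only
    the feature columns are transformed; metadata columns pass through.
    """
    cols = columns or [c for c in FEATURE_NAMES if c in table.columns]
    if reference is None:
        if "group" not in table.columns:
            raise FeatureError("no 'group' column and no explicit reference given")
        reference = table[table["group"] == "healthy"]
    try:
        scaler = HealthyReferenceScaler().fit(reference[cols].to_numpy(float))
    except FeatureError:
        # re-raise naming the actual feature
        std = reference[cols].std(ddof=1)
        bad = [c for c in cols if std[c] == 0]
        raise FeatureError(f"zero healthy std for feature(s) {bad}") from None
    out = table.copy()
    out[cols] = scaler.transform(table[cols].to_numpy(float))
    return out
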