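"""End-to-end feature extraction: IMU streams -> per-subject feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import aggregate_subject, compute_cycle_features
from .io import FEATURE_NAMES, ImuSeries, TrialMeta
from .kinematics import KinematicsConfig, compute_trajectory, correct_sensor_frame
from .segmentation import SegmentationConfig, detect_events, select_steady_cycles


def extract_series_features(series: ImuSeries, height: float,
                            seg_config: SegmentationConfig | None = None,
                            kin_config: KinematicsConfig | None = None) -> list[dict]:
    """Per-cycle feature dicts for one shank's stream of one trial."""
    seg_cfg = seg_config or SegmentationConfig()
    corrected, _ = correct_sensor_frame(series, config=kin_config)
    events = detect_events(corrected, seg_cfg)
    cycles = select_steady_cycles(events, corrected.time,
                                  n_skip=seg_cfg.n_skip, n_keep=seg_cfg.n_keep)
    out = []
    for cycle in cycles:
        kin = compute_trajectory(cycle, corrected, kin_config)
        out.append(compute_cycle_features(kin, cycle, corrected, height))
    return out


def extract_subject_row(trials: list, meta: TrialMeta,
                        seg_config: SegmentationConfig | None = None,
                        kin_config: KinematicsConfig | None = None) -> dict:
    """One subject's aggregated feature row from all trials and both legs.

    *trials* is a list of dicts mapping side ('left'/'right') to
    :class:`ImuSeries`.  The mean is taken flat over every steady cycle of
    every stream.
    """
    per_cycle = []
    for trial in trials:
        for series in trial.values():
            per_cycle.extend(
                extract_series_features(series, meta.height, seg_config, kin_config)
            )
    row = aggregate_subject(per_cycle)
    row["rated_level"] = meta.rated_level if meta.rated_level is not None else np.nan
    row["group"] = meta.group
    return row


def build_feature_table(subjects: list[tuple[list, TrialMeta]],
                        seg_config: SegmentationConfig | None = None,
                        kin_config: KinematicsConfig | None = None) -> pd.DataFrame:
    """Feature table (one row per subject) from (trials, meta) pairs."""
    rows, index = [], []
    for trials, meta in subjects:
        rows.append(extract_subject_row(trials, meta, seg_config, kin_config))
        index.append(meta.subject_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    return table[FEATURE_NAMES + ["rated_level", "group"]]
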