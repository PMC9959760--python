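"""Synthetic data with known ground truth, at two tiers.

*Feature tier* — per-subject feature vectors drawn around a known scoring
structure: a true direction w*, offset c* and demarcation values p* define
level bands in signed-distance (xhp) space; each subject's within-band
position is drawn from a Beta(2, 2) scaled to its level's band (severity
within a clinical level clusters centrally — borderline presentations are
rarer), outer bands are truncated at 1.5x the adjacent inner band width,
and isotropic Gaussian noise is added in standardised feature space.
Higher levels move along -w*: slower, shorter, flatter strides.

*Signal tier* — raw 100 Hz two-shank IMU trials built from an analytic
ankle trajectory (quintic swing arcs with zero velocity and acceleration
at the stance boundaries, ankle still during stance) and a sagittal shank
rotation profile whose mid-swing rate peak and toe-off/heel-strike dips
reproduce the classic shank gyro pattern.  Acceleration is the exact
second derivative of the trajectory plus gravity, rotated into the sensor
frame, so the extraction pipeline's own assumptions (zero velocity at
mid-stance, gravity-anchored attitude) hold exactly at zero noise.  Only
mediolateral-axis rotation is synthesised: RSX and RSY truth is 0, and
MPV, MVV, RSZ follow from the arc shape rather than being free targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import DataError
from .io import FEATURE_NAMES, G_MPS2, ImuSeries, TrialMeta
from .model import (
    DEFAULT_P,
    ScorerParams,
    inverse_bounded_distance,
    validate_params,
)

# ---------------------------------------------------------------------------
# feature tier
# ---------------------------------------------------------------------------

#: Plausible healthy means of the 12 features (normalised units / s / deg).
HEALTHY_MEAN = {
    "SL": 0.75, "GD": 1.05, "PSP": 40.0, "MH": 0.15, "RL": 0.04, "RSZ": 55.0,
    "RSY": 10.0, "RSX": 8.0, "MPV": 2.3, "MVV": 0.8, "MSV": 400.0, "MHD": 0.38,
}
#: Healthy between-subject standard deviations (same units).
HEALTHY_STD = {
    "SL": 0.06, "GD": 0.08, "PSP": 2.5, "MH": 0.015, "RL": 0.01, "RSZ": 5.0,
    "RSY": 2.0, "RSX": 2.0, "MPV": 0.20, "MVV": 0.08, "MSV": 35.0, "MHD": 0.04,
}

#: Default severity direction in standardised feature space: impairment
#: lowers stride length, clearance, shank excursion and swing velocity.
_DEFAULT_W = {
    "SL": -1.0, "MH": -1.0, "RSZ": -0.8, "MPV": -0.6, "MSV": -0.8, "MHD": -0.9,
}


def _default_direction() -> np.ndarray:
    w = np.array([_DEFAULT_W.get(name, 0.0) for name in FEATURE_NAMES])
    return w / np.linalg.norm(w)


@dataclass
class FeatureGenSpec:
    """Ground-truth scoring structure for the feature-tier generator."""

    n_per_level: dict = field(default_factory=lambda: {0: 10, 1: 10, 2: 10})
    w_true: np.ndarray = field(default_factory=_default_direction)
    c_true: float = 0.0
    p_true: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_P))
    noise: float = 0.0  #: isotropic noise std in standardised feature units
    #: alternative noise parameterisation: one std for all subjects, as a
    #: fraction of the mean inner level-band width (noise is a property of
    #: the measurement, not of the subject's severity)
    noise_band_frac: float | None = None
    outer_band_factor: float = 1.5
    healthy_frac: float = 0.5  #: fraction of level-0 rows labelled healthy
    seed: int = 0

    def __post_init__(self):
        self.w_true = np.asarray(self.w_true, dtype=float)
        norm = np.linalg.norm(self.w_true)
        if norm == 0:
            raise DataError("w_true must be non-zero")
        self.w_true = self.w_true / norm
        self.p_true = np.asarray(self.p_true, dtype=float)
        validate_params(ScorerParams(w=self.w_true, c=self.c_true, p=self.p_true))
        if any(n < 1 for n in self.n_per_level.values()):
            raise DataError("n_per_level entries must be >= 1")


def level_bands(spec: FeatureGenSpec) -> dict:
    """xhp interval of each level implied by the true demarcation values."""
    xb = inverse_bounded_distance(spec.p_true)
    widths = np.diff(xb)
    f = spec.outer_band_factor
    return {
        0: (xb[0] - f * widths[0], xb[0]),
        1: (xb[0], xb[1]),
        2: (xb[1], xb[2]),
        3: (xb[2], xb[3]),
        4: (xb[3], xb[3] + f * widths[2]),
    }


def generate_features(spec: FeatureGenSpec):
    """Draw a per-subject feature table with known generating levels.

    Returns ``(table, truth)``: *table* is indexed by subject_id with the
    12 feature columns plus ``rated_level`` and ``group``; *truth* records
    each row's generating level, noise-free signed distance ``xhp`` and
    the true parameters.  At zero noise, scoring each row with the true
    parameters reproduces its generating level exactly.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    bands = level_bands(spec)
    mu = np.array([HEALTHY_MEAN[n] for n in FEATURE_NAMES])
    sd = np.array([HEALTHY_STD[n] for n in FEATURE_NAMES])
    m = len(FEATURE_NAMES)
    sigma = spec.noise
    if spec.noise_band_frac is not None:
        inner = np.diff(inverse_bounded_distance(spec.p_true))
        sigma = spec.noise_band_frac * float(inner.mean())

    rows, meta, truth_rows = [], [], []
    sid = 0
    for level in sorted(spec.n_per_level):
        n = spec.n_per_level[level]
        if level not in bands:
            raise DataError(f"level {level} outside 0..4")
        lo, hi = bands[level]
        if hi <= lo:
            raise DataError(f"empty xhp band for level {level}")
        t = lo + (hi - lo) * rng.beta(2.0, 2.0, size=n)
        eps = rng.normal(0.0, sigma, size=(n, m)) if sigma > 0 else np.zeros((n, m))
        z = (t - spec.c_true)[:, None] * spec.w_true + eps
        x = mu + sd * z
        n_healthy = round(spec.healthy_frac * n) if level == 0 else 0
        for i in range(n):
            group = "healthy" if i < n_healthy else "pd"
            rows.append(x[i])
            meta.append({"subject_id": f"S{sid:03d}", "rated_level": level,
                         "group": group})
            truth_rows.append({"subject_id": f"S{sid:03d}", "level": level,
                               "xhp": t[i]})
            sid += 1

    table = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    for key in ("rated_level", "group"):
        table[key] = [m_[key] for m_ in meta]
    table.index = pd.Index([m_["subject_id"] for m_ in meta], name="subject_id")
    truth = {
        "rows": pd.DataFrame(truth_rows).set_index("subject_id"),
        "params": ScorerParams(w=spec.w_true, c=spec.c_true, p=spec.p_true,
                               features=list(FEATURE_NAMES)),
        "scale_mean": mu,
        "scale_std": sd,
    }
    return table, truth


# ---------------------------------------------------------------------------
# signal tier
# ---------------------------------------------------------------------------

#: Per-level presets for the signal generator (package defaults following
#: the qualitative trend of impaired gait; not clinical reference values).
LEVEL_PRESETS = {
    0: dict(stride_m=1.20, gd_s=1.05, swing_pct=40.0, mh_m=0.16, msv_dps=400.0),
    1: dict(stride_m=0.88, gd_s=1.20, swing_pct=38.0, mh_m=0.12, msv_dps=300.0),
    2: dict(stride_m=0.56, gd_s=1.40, swing_pct=35.0, mh_m=0.08, msv_dps=200.0),
}


@dataclass
class SignalGenSpec:
    """Targets and layout for one synthetic two-shank walking trial."""

    stride_m: float = 1.20
    gd_s: float = 1.05
    swing_pct: float = 40.0
    mh_m: float = 0.16
    msv_dps: float = 400.0
    mhd_frac: float = 0.5  #: fraction of the stride covered when MH occurs
    n_cycles: int = 16
    height_m: float = 1.70
    rate_hz: float = 100.0
    lead_s: float = 1.5  #: quiet standing before and after the walk
    noise_gyro_dps: float = 0.0
    noise_accel_g: float = 0.0
    misalign_deg: float = 0.0  #: sensor mounting misalignment about Z
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.swing_pct < 100:
            raise DataError("swing_pct must be in (0, 100)")
        if min(self.gd_s, self.mh_m, self.msv_dps, self.n_cycles) <= 0 \
                or self.stride_m < 0:
            raise DataError("targets must be positive")
        t_sw = self.gd_s * self.swing_pct / 100.0
        # velocity-bound sanity: the quintic arc's peak forward speed
        if self.stride_m > 0 and 1.875 * self.stride_m / t_sw > 10.0:
            raise DataError("inconsistent targets: implied swing speed > 10 m/s")
        if not 0.05 < self.mhd_frac < 0.95:
            raise DataError("mhd_frac must be in (0.05, 0.95)")


def _s5(u):
    """Quintic smoothstep: 0 -> 1 with zero first/second derivative at ends."""
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _s5d(u):
    return 30.0 * u**2 * (1.0 - u) ** 2


def _s5dd(u):
    return 60.0 * u * (1.0 - 3.0 * u + 2.0 * u**2)


class _Bump:
    """Raised-cosine-squared pulse with closed-form value and integral."""

    def __init__(self, center: float, width: float, amp: float):
        self.a, self.w, self.amp = center - width / 2.0, width, amp

    def value(self, t):
        tau = np.clip(t - self.a, 0.0, self.w)
        return self.amp * np.sin(np.pi * tau / self.w) ** 2

    def integral(self, t):
        tau = np.clip(t - self.a, 0.0, self.w)
        return self.amp * (tau / 2.0 - self.w / (4.0 * np.pi)
                           * np.sin(2.0 * np.pi * tau / self.w))


# right/left mounting: sensor X inferior, Y anterior (right) / posterior
# (left), Z mediolateral: lateral-out on both sides, so Z points along +L on
# the right shank and -L on the left.
_R0 = {
    "right": Rotation.from_matrix(np.array([[0.0, 1.0, 0.0],
                                            [-1.0, 0.0, 0.0],
                                            [0.0, 0.0, 1.0]])),
    "left": Rotation.from_matrix(np.array([[0.0, -1.0, 0.0],
                                           [-1.0, 0.0, 0.0],
                                           [0.0, 0.0, -1.0]])),
}
_L_AXIS = np.array([0.0, 0.0, 1.0])
_UP = np.array([0.0, 1.0, 0.0])


@dataclass
class TrialTruth:
    """Ground truth stored next to a generated trial."""

    features: dict  #: the 12 feature values the pipeline should recover
    hs_times: dict  #: side -> array of heel-strike times, s
    to_times: dict  #: side -> array of toe-off times, s
    theta_deg: dict  #: side -> sagittal shank angle per sample, deg
    pos_global: dict  #: side -> (n, 3) ankle position in (P, V, L), m
    spec: SignalGenSpec = None


def _side_signals(spec: SignalGenSpec, t: np.ndarray, t0: float):
    """Analytic gyro rate, shank angle, ankle pos/acc for one side's walk."""
    gd, t_sw = spec.gd_s, spec.gd_s * spec.swing_pct / 100.0
    t_st = gd - t_sw
    u_pk = (0.5 if abs(spec.mhd_frac - 0.5) < 1e-12
            else brentq(lambda u: _s5(u) - spec.mhd_frac, 1e-6, 1 - 1e-6))

    # gyro profile: dips at each HS and TO, main positive pulse mid-swing
    w_m = 0.6 * t_sw
    w_d = min(0.3 * t_st, 0.2)
    d_amp = spec.msv_dps * w_m / (2.0 * w_d)  # zero net rotation per cycle
    bumps = []
    hs_times = np.array([t0 + k * gd for k in range(spec.n_cycles + 1)])
    to_times = np.array([t0 + k * gd + t_st for k in range(spec.n_cycles)])
    for k, hs in enumerate(hs_times):
        # boundary heel strikes (walk start/end) get half-weight dips so the
        # net shank rotation over the whole trial is zero
        amp = -d_amp if 0 < k < len(hs_times) - 1 else -d_amp / 2.0
        bumps.append(_Bump(hs, w_d, amp))
    for to in to_times:
        bumps.append(_Bump(to, w_d, -d_amp))
        bumps.append(_Bump(to + t_sw / 2.0, w_m, spec.msv_dps))

    rate_dps = np.zeros_like(t)
    theta_deg = np.zeros_like(t)
    for b in bumps:
        rate_dps += b.value(t)
        theta_deg += b.integral(t)

    # ankle path: still in stance, quintic arc in swing
    pos = np.zeros((t.size, 3))
    acc = np.zeros((t.size, 3))
    k = np.floor((t - t0) / gd).astype(int)
    k = np.clip(k, 0, spec.n_cycles - 1)
    phase = t - t0 - k * gd
    walked = (t >= t0) & (t < t0 + spec.n_cycles * gd)
    swing = walked & (phase >= t_st)
    after = t >= t0 + spec.n_cycles * gd
    u = np.clip((phase - t_st) / t_sw, 0.0, 1.0)

    pos[walked, 0] = k[walked] * spec.stride_m
    pos[swing, 0] += spec.stride_m * _s5(u[swing])
    pos[after, 0] = spec.n_cycles * spec.stride_m
    acc[swing, 0] = spec.stride_m * _s5dd(u[swing]) / t_sw**2

    uu = u[swing]
    up = np.where(uu < u_pk, _s5(uu / u_pk), _s5((1.0 - uu) / (1.0 - u_pk)))
    pos[swing, 1] = spec.mh_m * up
    upp = np.where(uu < u_pk, _s5dd(uu / u_pk) / u_pk**2,
                   _s5dd((1.0 - uu) / (1.0 - u_pk)) / (1.0 - u_pk) ** 2)
    acc[swing, 1] = spec.mh_m * upp / t_sw**2

    return rate_dps, theta_deg, pos, acc, hs_times, to_times, u_pk, t_sw


def _truth_features(spec: SignalGenSpec, t, rate_dps, theta_deg, pos, u_pk, t_sw):
    """The 12 feature values implied by the analytic construction."""
    h = spec.height_m
    mpv = 1.875 * spec.stride_m / t_sw  # quintic peak forward speed
    mvv = spec.mh_m * 1.875 / (u_pk * t_sw)
    gd = spec.gd_s
    in_cycle = (t >= spec.lead_s) & (t <= spec.lead_s + gd)
    rsz = float(np.ptp(theta_deg[in_cycle]))
    return {
        "SL": spec.stride_m / h,
        "GD": gd,
        "PSP": spec.swing_pct,
        "MH": spec.mh_m / h,
        "RL": 0.0,
        "RSZ": rsz,
        "RSY": 0.0,
        "RSX": 0.0,
        "MPV": mpv / h,
        "MVV": mvv / h,
        "MSV": spec.msv_dps,
        "MHD": spec.mhd_frac * spec.stride_m / h,
    }


def generate_imu_trial(spec: SignalGenSpec):
    """Synthesise one trial's left and right shank IMU streams plus truth.

    Returns ``(series_by_side, truth)`` where ``series_by_side`` maps
    'left'/'right' to :class:`ImuSeries`.  The left sensor is mirrored
    (mediolateral axis flipped), the right leg leads by half a cycle, and
    both streams start and end with quiet standing long enough for static
    frame calibration.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.rate_hz
    total = 2 * spec.lead_s + (spec.n_cycles + 0.5) * spec.gd_s
    t = np.arange(int(round(total / dt)) + 1) * dt

    starts = {"right": spec.lead_s, "left": spec.lead_s + spec.gd_s / 2.0}
    series, truth_theta, truth_pos, truth_hs, truth_to = {}, {}, {}, {}, {}
    feats = None
    for side, t0 in starts.items():
        rate_dps, theta_deg, pos, acc, hs_times, to_times, u_pk, t_sw = \
            _side_signals(spec, t, t0)
        if feats is None:
            feats = _truth_features(spec, t, rate_dps, theta_deg, pos, u_pk, t_sw)
        theta = np.radians(theta_deg)
        rots = (Rotation.from_rotvec(np.outer(theta, _L_AXIS)) * _R0[side])
        omega_global = np.outer(np.radians(rate_dps), _L_AXIS)
        f_global = acc + G_MPS2 * _UP
        gyro = rots.inv().apply(omega_global)
        accel = rots.inv().apply(f_global)
        if spec.misalign_deg:
            mis = Rotation.from_euler("z", spec.misalign_deg, degrees=True)
            gyro, accel = mis.apply(gyro), mis.apply(accel)
        if spec.noise_gyro_dps > 0:
            gyro = gyro + np.radians(rng.normal(0, spec.noise_gyro_dps, gyro.shape))
        if spec.noise_accel_g > 0:
            accel = accel + rng.normal(0, spec.noise_accel_g * G_MPS2, accel.shape)
        series[side] = ImuSeries(time=t.copy(), gyro=gyro, accel=accel,
                                 side=side, rate_hz=spec.rate_hz)
        truth_theta[side] = theta_deg
        truth_pos[side] = pos
        truth_hs[side] = hs_times
        truth_to[side] = to_times

    truth = TrialTruth(features=feats, hs_times=truth_hs, to_times=truth_to,
                       theta_deg=truth_theta, pos_global=truth_pos, spec=spec)
    return series, truth


def generate_subject_trials(level: int, subject_id: str, n_trials: int = 3,
                            seed: int = 0, **overrides):
    """Convenience: trials for one subject at a per-level gait preset.

    Returns ``(trials, meta)``; each trial is the ``(series_by_side,
    truth)`` pair of :func:`generate_imu_trial`.
    """
    if level not in LEVEL_PRESETS:
        raise DataError(f"no preset for level {level}")
    preset = dict(LEVEL_PRESETS[level])
    preset.update(overrides)
    trials = []
    for k in range(n_trials):
        spec = SignalGenSpec(seed=seed + 1000 * k, **preset)
        trials.append(generate_imu_trial(spec))
    meta = TrialMeta(subject_id=subject_id,
                     height=preset.get("height_m", 1.70),
                     rated_level=level,
                     group="healthy" if level == 0 else "pd")
    return trials, meta
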