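"""Shank orientation and ankle trajectory per gait cycle.

Strapdown integration with per-cycle zero-velocity updates (ZUPT): during
mid-stance the foot is flat and the ankle momentarily still, so the
attitude can be anchored to gravity from the accelerometer and the
integrated velocity reset to zero there.  Residual velocity drift between
consecutive zero-velocity instants is removed with a linear model, then
acceleration is double-integrated to the ankle path.  The global frame is
P (progression: the horizontal direction joining the two successive ankle
landing points of the stride), V (vertical, up positive) and L (lateral,
completing a right-handed frame); heading is unobservable without a
magnetometer, which is why P is defined per cycle from the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import CalibrationError, KinematicsError
from .io import ImuSeries
from .segmentation import GaitCycle

UP = np.array([0.0, 1.0, 0.0])  # global vertical in the working frame
DOWN_X = np.array([-1.0, 0.0, 0.0])  # shank-aligned sensor: static accel direction


@dataclass
class KinematicsConfig:
    zupt_window_s: float = 0.1
    gravity_mps2: float = 9.80665
    drift_model: str = "linear"  # linear | none
    zv_max_dps: float = 40.0  #: max smoothed gyro magnitude at a zero-velocity instant
    static_gyro_dps: float = 5.0
    min_static_s: float = 1.0


@dataclass
class CycleKinematics:
    """Per-cycle shank rotation angles and ankle trajectory in the P/V/L frame."""

    time: np.ndarray  #: cycle time stamps, s
    rot_deg: np.ndarray  #: (n, 3) rotation angles about sensor X/Y/Z, deg, zeroed at HS
    pos_pvl: np.ndarray  #: (n, 3) ankle displacement, m, zeroed at HS
    vel_pvl: np.ndarray  #: (n, 3) ankle velocity, m/s
    zv_index: int  #: zero-velocity sample, absolute index into the series
    to_offset: int  #: TO position relative to cycle start


def _shortest_arc(a: np.ndarray, b: np.ndarray) -> Rotation:
    """Minimal rotation taking unit vector *a* onto unit vector *b*."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        if dot > 0:
            return Rotation.identity()
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * axis / np.linalg.norm(axis))
    angle = np.arctan2(norm, dot)
    return Rotation.from_rotvec(angle * cross / norm)


def find_static_window(series: ImuSeries, config: KinematicsConfig | None = None):
    """Longest contiguous quasi-static run (low gyro), as a slice, or None."""
    cfg = config or KinematicsConfig()
    quiet = np.linalg.norm(series.gyro_dps, axis=1) < cfg.static_gyro_dps
    best, start, n = None, None, len(series)
    i = 0
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            if best is None or (j - i) > (best.stop - best.start):
                best = slice(i, j)
            i = j
        else:
            i += 1
    if best is None:
        return None
    if series.time[best.stop - 1] - series.time[best.start] < cfg.min_static_s:
        return None
    return best


def correct_sensor_frame(series: ImuSeries,
                         rotation: Rotation | None = None,
                         config: KinematicsConfig | None = None):
    """Align the sensor frame with the shank long axis.

    During quiet standing the specific force points along the shank, so the
    measured gravity direction fixes the misalignment up to an (irrelevant)
    roll about the shank axis; the minimal rotation mapping the static
    accelerometer mean onto (-1, 0, 0) is applied to both gyro and accel.
    An explicit *rotation* override skips the static estimation.

    Returns ``(corrected_series, rotation)``.
    """
    cfg = config or KinematicsConfig()
    if rotation is None:
        window = find_static_window(series, cfg)
        if window is None:
            raise CalibrationError(
                "no quasi-static window found and no override rotation given"
            )
        mean_accel = series.accel[window].mean(axis=0)
        norm = np.linalg.norm(mean_accel)
        if norm < 0.5 * cfg.gravity_mps2:
            raise CalibrationError(
                f"static specific force {norm:.2f} m/s^2 too small: gravity unobservable"
            )
        rotation = _shortest_arc(mean_accel / norm, DOWN_X)
    corrected = ImuSeries(
        time=series.time,
        gyro=rotation.apply(series.gyro),
        accel=rotation.apply(series.accel),
        side=series.side,
        rate_hz=series.rate_hz,
    )
    return corrected, rotation


def _smoothed_gyro_mag(series: ImuSeries, window_s: float) -> np.ndarray:
    mag = np.linalg.norm(series.gyro_dps, axis=1)
    w = max(1, int(round(window_s / series.dt)))
    kernel = np.ones(w) / w
    return np.convolve(mag, kernel, mode="same")


def _zero_velocity_index(smoothed: np.ndarray, lo: int, hi: int,
                         zv_max_dps: float) -> int:
    """Sample in [lo, hi) minimising the smoothed gyro magnitude."""
    if hi <= lo:
        raise KinematicsError("empty stance window: no zero-velocity instant")
    k = int(lo + np.argmin(smoothed[lo:hi]))
    if smoothed[k] > zv_max_dps:
        raise KinematicsError(
            f"no zero-velocity instant: min smoothed gyro "
            f"{smoothed[k]:.1f} deg/s exceeds {zv_max_dps:g} deg/s"
        )
    return k


def integrate_orientation(cycle: GaitCycle, series: ImuSeries) -> np.ndarray:
    """Cumulative trapezoidal integral of each gyro axis over the cycle, degrees.

    Returns an ``(n, 3)`` array zeroed at the cycle-start heel strike.
    """
    sl = slice(cycle.start_hs, cycle.end_hs + 1)
    t = series.time[sl]
    gyro_deg = series.gyro_dps[sl]
    out = np.zeros_like(gyro_deg)
    dt = np.diff(t)[:, None]
    out[1:] = np.cumsum(0.5 * (gyro_deg[1:] + gyro_deg[:-1]) * dt, axis=0)
    return out


def _strapdown_attitudes(series: ImuSeries, anchor: int, lo: int, hi: int,
                         r_anchor: Rotation) -> list:
    """Body-to-global attitude at each sample in [lo, hi], anchored at *anchor*."""
    n = hi - lo + 1
    rots = [None] * n
    rots[anchor - lo] = r_anchor
    t, gyro = series.time, series.gyro
    r = r_anchor
    for k in range(anchor, hi):  # forward
        dt = t[k + 1] - t[k]
        w_mid = 0.5 * (gyro[k] + gyro[k + 1])
        r = r * Rotation.from_rotvec(w_mid * dt)
        rots[k + 1 - lo] = r
    r = r_anchor
    for k in range(anchor, lo, -1):  # backward
        dt = t[k] - t[k - 1]
        w_mid = 0.5 * (gyro[k] + gyro[k - 1])
        r = r * Rotation.from_rotvec(-w_mid * dt)
        rots[k - 1 - lo] = r
    return rots


def compute_trajectory(cycle: GaitCycle, series: ImuSeries,
                       config: KinematicsConfig | None = None) -> CycleKinematics:
    """Ankle trajectory of one cycle in the P/V/L frame with ZUPT drift removal.

    The attitude is anchored to gravity at the mid-stance zero-velocity
    instant, propagated across the cycle by strapdown integration of the
    angular rate, and gravity-compensated acceleration is integrated twice.
    Velocity is forced to zero at the anchor; the residual at the *next*
    cycle's zero-velocity instant is removed linearly in time
    (``drift_model='linear'``).  Requires the series to extend into the
    stance following the cycle for the second anchor.
    """
    cfg = config or KinematicsConfig()
    g_up = cfg.gravity_mps2 * UP
    smoothed = _smoothed_gyro_mag(series, cfg.zupt_window_s)
    i0, i1, i2 = cycle.start_hs, cycle.to, cycle.end_hs

    zv1 = _zero_velocity_index(smoothed, i0, i1, cfg.zv_max_dps)
    # second anchor in the following stance (within one cycle length past end HS)
    hi2 = min(len(series) - 1, i2 + (i2 - i0))
    use_drift = cfg.drift_model == "linear" and hi2 > i2
    if use_drift:
        zv2 = _zero_velocity_index(smoothed, i2, hi2 + 1, cfg.zv_max_dps)
    else:
        zv2 = i2

    # attitude anchor from the accelerometer at the zero-velocity instant
    w = max(1, int(round(0.5 * cfg.zupt_window_s / series.dt)))
    f_anchor = series.accel[max(i0, zv1 - w):zv1 + w + 1].mean(axis=0)
    if np.linalg.norm(f_anchor) < 0.5 * cfg.gravity_mps2:
        raise KinematicsError("specific force at zero-velocity instant too small")
    r_anchor = _shortest_arc(f_anchor / np.linalg.norm(f_anchor), UP)

    lo, hi = i0, zv2
    rots = _strapdown_attitudes(series, zv1, lo, hi, r_anchor)
    t = series.time[lo:hi + 1]
    f_body = series.accel[lo:hi + 1]
    f_glob = np.stack([r.apply(f) for r, f in zip(rots, f_body)])
    a_glob = f_glob - g_up

    # velocity: trapezoid, shifted so v = 0 at the anchor
    v = np.zeros_like(a_glob)
    dt = np.diff(t)[:, None]
    v[1:] = np.cumsum(0.5 * (a_glob[1:] + a_glob[:-1]) * dt, axis=0)
    v -= v[zv1 - lo]

    if use_drift and zv2 > zv1:
        drift = v[zv2 - lo].copy()
        span = t[zv2 - lo] - t[zv1 - lo]
        ramp = np.clip((t - t[zv1 - lo]) / span, 0.0, None)[:, None]
        v = v - drift * ramp

    p = np.zeros_like(v)
    p[1:] = np.cumsum(0.5 * (v[1:] + v[:-1]) * dt, axis=0)
    p -= p[0]

    n_cycle = i2 - i0 + 1
    delta = p[n_cycle - 1] - p[0]
    horiz = delta - np.dot(delta, UP) * UP
    if np.linalg.norm(horiz) > 1e-9:
        p_axis = horiz / np.linalg.norm(horiz)
    else:
        p_axis = np.array([1.0, 0.0, 0.0])  # degenerate: no progression
    l_axis = np.cross(p_axis, UP)
    basis = np.stack([p_axis, UP, l_axis])  # rows: P, V, L

    return CycleKinematics(
        time=t[:n_cycle],
        rot_deg=integrate_orientation(cycle, series),
        pos_pvl=p[:n_cycle] @ basis.T,
        vel_pvl=v[:n_cycle] @ basis.T,
        zv_index=zv1,
        to_offset=i1 - i0,
    )
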