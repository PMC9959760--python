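"""Heel-strike / toe-off detection and gait-cycle windowing.

The shank mediolateral (Z) angular velocity traces a cyclic pattern during
walking: a large positive peak at mid-swing flanked by two negative dips,
the earlier at toe-off (TO) and the later at heel-strike (HS).  Events are
read off a zero-phase low-pass filtered copy of gyro_z; the raw samples are
never modified.  A trial is then carved into HS-to-HS cycles, the first
four (accelerating) steps are discarded and up to ten steady cycles kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .errors import InsufficientDataError, SegmentationError
from .io import ImuSeries


@dataclass
class SegmentationConfig:
    lowpass_hz: float = 10.0
    peak_prominence_dps: float = 50.0
    min_step_s: float = 0.4
    n_skip: int = 4
    n_keep: int = 10


@dataclass
class GaitEvents:
    """Detected events, as sample indices into the source series.

    HS and TO alternate in time starting with an HS; a trailing TO (from a
    boundary-truncated final cycle) may follow the last HS.
    """

    hs_indices: np.ndarray
    to_indices: np.ndarray
    flipped: bool = False  #: True if gyro_z sign was auto-corrected

    def __post_init__(self):
        self.hs_indices = np.asarray(self.hs_indices, dtype=int)
        self.to_indices = np.asarray(self.to_indices, dtype=int)


@dataclass
class GaitCycle:
    """One HS-to-HS window; TO splits stance [start_hs, to) from swing [to, end_hs)."""

    start_hs: int
    to: int
    end_hs: int

    def __post_init__(self):
        if not self.start_hs < self.to < self.end_hs:
            raise SegmentationError(
                f"cycle indices must satisfy start_hs < to < end_hs, got "
                f"({self.start_hs}, {self.to}, {self.end_hs})"
            )

    def duration_s(self, time: np.ndarray) -> float:
        return float(time[self.end_hs] - time[self.start_hs])


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    # zero-phase 4th-order Butterworth (2nd order each direction)
    b, a = butter(4, cutoff_hz / (fs / 2.0), btype="low")
    return filtfilt(b, a, x)


def detect_events(series: ImuSeries, config: SegmentationConfig | None = None) -> GaitEvents:
    """Detect HS and TO events from the cyclic gyro_z pattern.

    Mid-swing positive peaks are located first (prominence and minimum
    separation from *config*); each peak's TO is the prominent trough
    immediately before it and its HS the trough immediately after it.  If
    the sensor was mounted mirrored (left shank), the dominant peaks are
    negative and the working copy of the signal is flipped first.
    """
    cfg = config or SegmentationConfig()
    fs = 1.0 / series.dt
    if len(series) < 2 * fs:
        raise SegmentationError("series shorter than 2 s")
    gz = np.degrees(series.gyro[:, 2])
    sig = _lowpass(gz, fs, cfg.lowpass_hz)

    # mounting-side sign: mid-swing peaks must be positive
    ipk, _ = find_peaks(np.abs(sig), prominence=cfg.peak_prominence_dps,
                        distance=max(1, int(cfg.min_step_s * fs)))
    flipped = False
    if ipk.size:
        top3 = ipk[np.argsort(np.abs(sig[ipk]))[-3:]]
        if np.median(sig[top3]) < 0:
            sig = -sig
            flipped = True

    min_dist = max(1, int(cfg.min_step_s * fs))
    peaks, pprops = find_peaks(sig, prominence=cfg.peak_prominence_dps,
                               distance=min_dist)
    if peaks.size == 0:
        raise SegmentationError("no swing peaks found: no gait present")

    # troughs: local minima clearly deeper than filter ripple, which scales
    # with the swing peaks themselves
    trough_prom = max(0.05 * cfg.peak_prominence_dps,
                      0.15 * float(np.median(pprops["prominences"])))
    troughs, tprops = find_peaks(-sig, prominence=trough_prom)
    if troughs.size == 0:
        raise SegmentationError("no troughs flanking the swing peaks")

    hs, to = [], []
    for pk in peaks:
        before = troughs[troughs < pk]
        after = troughs[troughs > pk]
        if before.size:
            to.append(before[-1])
        if after.size:
            hs.append(after[0])
    # the HS opening the first detected cycle: the most prominent trough
    # preceding the first TO (small filter-ripple minima are skipped)
    if to:
        mask = troughs < to[0]
        if mask.any():
            prom = tprops["prominences"][mask]
            hs.append(int(troughs[mask][np.argmax(prom)]))

    events = sorted(set((i, "hs") for i in hs) | set((i, "to") for i in to))
    # enforce alternation starting with HS
    seq = []
    for idx, kind in events:
        if not seq and kind != "hs":
            continue
        if seq and seq[-1][1] == kind:
            raise SegmentationError(
                f"events do not interleave: consecutive {kind} at samples "
                f"{seq[-1][0]} and {idx}"
            )
        seq.append((idx, kind))
    hs_idx = [i for i, k in seq if k == "hs"]
    to_idx = [i for i, k in seq if k == "to"]
    if not hs_idx or not to_idx:
        raise SegmentationError("interleaving HS/TO sequence unsatisfiable")
    return GaitEvents(hs_indices=hs_idx, to_indices=to_idx, flipped=flipped)


def cycles_from_events(events: GaitEvents, time: np.ndarray,
                       min_duration_s: float = 0.4,
                       max_duration_s: float = 4.0) -> list[GaitCycle]:
    """All full HS-to-HS cycles with an interior TO, duration-filtered."""
    cycles = []
    for a, b in zip(events.hs_indices[:-1], events.hs_indices[1:]):
        interior = [t for t in events.to_indices if a < t < b]
        if len(interior) != 1:
            continue
        dur = time[b] - time[a]
        if not min_duration_s < dur < max_duration_s:
            continue
        cycles.append(GaitCycle(start_hs=int(a), to=int(interior[0]), end_hs=int(b)))
    return cycles


def select_steady_cycles(events: GaitEvents, time: np.ndarray,
                         n_skip: int = 4, n_keep: int = 10) -> list[GaitCycle]:
    """Drop the first *n_skip* accelerating steps and keep up to *n_keep* steady ones.

    A "step" is one full cycle of this leg's IMU.  Raises
    :class:`InsufficientDataError` when no steady step remains; emits a
    warning when fewer than *n_keep* exist.
    """
    cycles = cycles_from_events(events, time)
    if len(cycles) < n_skip + 1:
        raise InsufficientDataError(
            f"only {len(cycles)} full cycles detected; need more than {n_skip}"
        )
    steady = cycles[n_skip:n_skip + n_keep]
    if len(steady) < n_keep:
        warnings.warn(
            f"only {len(steady)} steady cycles available (wanted {n_keep})",
            stacklevel=2,
        )
    return steady
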