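"""Recording preprocessing ahead of Up/Down-state segmentation.

Four stages, each usable on its own:

* ``remove_spikes`` — action potentials are located where the temporal
  derivative of the 100 Hz-8 kHz band-passed V_m exceeds 10 SD above its
  mean, and 3 ms after each onset is replaced by linear interpolation.
* ``notch_mains`` — cascade of zero-phase 8-pole bandstops at 50 Hz and
  its harmonics (45-55, 95-105, ..., 295-305 Hz); bands above Nyquist are
  skipped with a warning.
* ``uds_band_filter`` — zero-phase 0.05-2 Hz band-pass isolating the slow
  oscillation.
* ``find_desynchronized`` — multitaper spectrogram in 15 s windows
  (time-bandwidth 4, 7 tapers); windows whose maximum 0.05-2 Hz log power
  z-scores below a threshold, or whose low/high-band feature ratio falls
  below a floor, are flagged as desynchronized.

All filters are applied forward-backward (scipy ``sosfiltfilt``), so an
"8-pole" bandstop is realized as a 4th-order Butterworth passed twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import signal as sp_signal

from .intervals import EpochSet
from .surrogate import Recording

__all__ = ["remove_spikes", "notch_mains", "uds_band_filter",
           "find_desynchronized", "DesyncConfig"]

MAINS_BANDS = [(45.0, 55.0), (95.0, 105.0), (145.0, 155.0),
               (195.0, 205.0), (245.0, 255.0), (295.0, 305.0)]


def _copy_with(rec: Recording, signal: np.ndarray) -> Recording:
    return Recording(signal=signal, fs=rec.fs, role=rec.role,
                     truth=rec.truth, truth_weights=rec.truth_weights,
                     truth_spikes=rec.truth_spikes,
                     truth_desync=rec.truth_desync)


def remove_spikes(vm: Recording, threshold_sd: float = 10.0,
                  blank_ms: float = 3.0) -> Tuple[Recording, np.ndarray]:
    """Detect and excise action potentials from a V_m recording.

    The detector thresholds the derivative of the 100 Hz-8 kHz band-passed
    signal at ``threshold_sd`` SDs above its mean (SD of the derivative
    itself); each onset starts a ``blank_ms`` window replaced by linear
    interpolation between the flanking samples, with overlapping windows
    merged.  Idempotent: a second pass finds nothing.
    """
    if vm.role != "vm":
        raise ValueError("remove_spikes expects a vm recording")
    if vm.fs < 1000.0:
        raise ValueError("fs must be >= 1 kHz for the 100 Hz-8 kHz band")
    hi = min(8000.0, 0.45 * vm.fs)
    if hi < 8000.0:
        warnings.warn(f"band upper edge capped at {hi:.0f} Hz (0.45*fs)")
    sos = sp_signal.butter(2, [100.0, hi], btype="bandpass",
                           fs=vm.fs, output="sos")
    band = sp_signal.sosfiltfilt(sos, vm.signal)
    deriv = np.diff(band)
    thresh = deriv.mean() + threshold_sd * deriv.std()
    raw = np.flatnonzero((deriv[1:] > thresh) & (deriv[:-1] <= thresh)) + 1
    # filter ringing re-crossings: one onset per blank window
    min_gap = int(round(blank_ms / 1000.0 * vm.fs))
    onsets = []
    for i in raw:
        if not onsets or i - onsets[-1] > min_gap:
            onsets.append(i)
    onsets = np.array(onsets, dtype=int)

    blank = int(round(blank_ms / 1000.0 * vm.fs))
    # 1 ms pre-onset guard: the derivative threshold crossing sits a
    # fraction of a millisecond into the rising edge of the waveform
    guard = max(int(round(0.001 * vm.fs)), 1)
    clean = vm.signal.copy()
    merged: List[Tuple[int, int]] = []
    for i in onsets:
        lo, hi_i = i - guard, i + blank
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], hi_i)
        else:
            merged.append((lo, hi_i))
    for lo, hi_i in merged:
        a = max(lo - 1, 0)
        b = min(hi_i + 1, len(clean) - 1)
        clean[a:b + 1] = np.linspace(clean[a], clean[b], b - a + 1)
    spike_times = onsets / vm.fs
    return _copy_with(vm, clean), spike_times


def notch_mains(rec: Recording) -> Recording:
    """Zero-phase bandstop cascade removing 50 Hz mains and harmonics.

    The full six-band cascade needs fs > 610 Hz; at lower rates the bands
    reaching Nyquist are skipped with a warning.  Below 150 Hz even the
    fundamental notch is meaningless and the call is rejected.
    """
    if rec.fs <= 150.0:
        raise ValueError("fs too low for even the 45-55 Hz notch")
    out = rec.signal.copy()
    for lo, hi in MAINS_BANDS:
        if hi >= 0.5 * rec.fs:
            warnings.warn(f"skipping {lo:.0f}-{hi:.0f} Hz notch above Nyquist")
            continue
        sos = sp_signal.butter(4, [lo, hi], btype="bandstop",
                               fs=rec.fs, output="sos")
        out = sp_signal.sosfiltfilt(sos, out)
    return _copy_with(rec, out)


def uds_band_filter(rec: Recording, band: Tuple[float, float] = (0.05, 2.0),
                    min_duration: float = 60.0) -> Recording:
    """Zero-phase band-pass isolating the slow-oscillation band."""
    if rec.duration < min_duration:
        raise ValueError(
            f"recording shorter than {min_duration} s: filter transients "
            "would dominate")
    sos = sp_signal.butter(2, band, btype="bandpass", fs=rec.fs,
                           output="sos")
    return _copy_with(rec, sp_signal.sosfiltfilt(sos, rec.signal))


@dataclass(frozen=True)
class DesyncConfig:
    """Decision rule for desynchronized-epoch rejection.

    Each window of the unit-variance signal yields two features: the
    maximum log power in 0.05-2 Hz (f_low) and the integrated log power in
    4-40 Hz (f_high).  A window is desynchronized when f_low - f_high
    falls below ``ratio_floor`` (slow-band dominance lost; each window is
    normalized to unit SD first, so the floor is insensitive to amplitude
    and separates UDS at >= +25 from 1/f activity at <= -40), or - when
    ``low_z_threshold`` is set - when f_low z-scores below it relative to
    the rest of the recording.  The relative rule is off by default: on
    stationary recordings it flags a fixed quantile of perfectly good
    windows.
    """

    window_s: float = 15.0
    overlap: float = 0.5
    nw: float = 4.0
    n_tapers: int = 7
    low_z_threshold: float | None = None
    ratio_floor: float = 0.0
    min_epoch_s: float = 25.0


def _multitaper_features(x: np.ndarray, fs: float, cfg: DesyncConfig):
    n_win = int(cfg.window_s * fs)
    step = max(int(n_win * (1.0 - cfg.overlap)), 1)
    tapers = sp_signal.windows.dpss(n_win, cfg.nw, Kmax=cfg.n_tapers)
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    low = (freqs >= 0.05) & (freqs <= 2.0)
    high = (freqs >= 4.0) & (freqs <= 40.0)
    df = freqs[1] - freqs[0]
    centers, f_low, f_high = [], [], []
    for start in range(0, len(x) - n_win + 1, step):
        seg = x[start:start + n_win]
        seg = seg - seg.mean()
        sd = seg.std()
        if sd > 0:
            seg = seg / sd
        spec = np.mean(np.abs(np.fft.rfft(tapers * seg[None, :],
                                          axis=1)) ** 2, axis=0)
        logp = np.log(spec + 1e-300)
        centers.append((start + n_win / 2) / fs)
        f_low.append(logp[low].max())
        f_high.append(logp[high].sum() * df)
    return (np.array(centers), np.array(f_low), np.array(f_high),
            n_win / fs, step / fs)


def find_desynchronized(lfp: Recording,
                        cfg: DesyncConfig = DesyncConfig()) -> EpochSet:
    """Locate epochs without UDS from multitaper spectral features.

    Returns a sorted, disjoint set of desynchronized intervals; adjacent
    flagged windows merge, and merged runs shorter than ``min_epoch_s``
    are discarded (a single window without a state transition is quiet,
    not desynchronized).  An empty set means the whole recording is
    synchronized.
    """
    if lfp.duration < 2 * cfg.window_s:
        raise ValueError("recording must span at least two windows")
    x = lfp.signal - lfp.signal.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    centers, f_low, f_high, win_s, step_s = _multitaper_features(
        x, lfp.fs, cfg)
    flagged = (f_low - f_high) < cfg.ratio_floor
    if cfg.low_z_threshold is not None:
        z_low = (f_low - f_low.mean()) / (f_low.std() or 1.0)
        flagged |= z_low < cfg.low_z_threshold
    intervals: List[Tuple[float, float]] = []
    for c, bad in zip(centers, flagged):
        if not bad:
            continue
        start, end = c - win_s / 2, c + win_s / 2
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], end)
        else:
            intervals.append((start, end))
    intervals = [(max(0.0, a), min(lfp.duration, b)) for a, b in intervals]
    # a single quiet window (one long Down state) is not a desynchronized
    # epoch; require a sustained run of flagged windows
    intervals = [iv for iv in intervals if iv[1] - iv[0] >= cfg.min_epoch_s]
    return EpochSet(intervals, label="desynchronized")
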