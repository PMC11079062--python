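"""Synthetic paired V_m/LFP recordings with ground truth.

Renders simulated network activity as the two observables the analysis
pipeline consumes: an intracellular membrane potential (mV) for the
efferent network and an extracellular LFP (z-scored a.u.) for the afferent
one.  The rendering emulates the statistical structure of in vivo
urethane-anesthesia recordings: a bimodal mV distribution with
state-conditional means (MEC-like defaults, Up -52.4 mV / Down -74.2 mV),
broadband observation noise, optional action-potential waveforms riding on
Up states, 50 Hz mains contamination, pink (1/f) background on the LFP,
and optional desynchronized epochs in which the UDS rhythm of both
channels is replaced by low-amplitude 1/f noise.

What it does not emulate: spike afterpotentials and bursting, slow
electrode drift, depth-dependent LFP polarity and spectral structure
beyond 1/f, and movement artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .intervals import StateSequence, EpochSet
from .model_core import ModelParams, fixed_points
from .simulator import (SimTrace, simulate_coupled, binarize_states,
                        derive_seed)

__all__ = ["Recording", "RenderConfig", "render_vm", "render_lfp",
           "make_cell_dataset", "CellRecording"]


@dataclass
class Recording:
    """A sampled single-channel signal with acquisition metadata.

    ``role`` is 'vm' (membrane potential, mV) or 'lfp' (a.u.).  ``truth``
    optionally carries the generating state sequence; ``truth_weights`` the
    generating (W_EXT, W_INT); ``truth_spikes`` inserted spike times; and
    ``truth_desync`` the inserted desynchronized epochs.
    """

    signal: np.ndarray
    fs: float
    role: str
    truth: Optional[StateSequence] = None
    truth_weights: Optional[Tuple[float, float]] = None
    truth_spikes: Optional[np.ndarray] = None
    truth_desync: Optional[EpochSet] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.role not in ("vm", "lfp"):
            raise ValueError(f"unknown role {self.role!r}")
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("recording contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.signal)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.signal) / self.fs


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for surrogate recordings.

    mV anchors default to the MECIII values (Up -52.4, Down -74.2 mV).
    ``obs_noise_mV`` is broadband Gaussian observation noise;
    ``spike_rate_gain`` converts supra-threshold excitatory activity into
    an inhomogeneous Poisson firing rate (spikes/s per unit activity above
    theta_E); spikes are 1 ms triangular +40 mV waveforms.  ``mains_amp``
    is the 50 Hz contamination amplitude (mV on V_m, a.u. on LFP);
    ``lfp_noise`` the relative SD of the pink background added to the
    z-scored LFP; ``lfp_polarity`` +1 maps Up states to positive
    deflections.
    """

    up_mV: float = -52.4
    down_mV: float = -74.2
    obs_noise_mV: float = 1.0
    spike_rate_gain: float = 30.0
    spike_amp_mV: float = 40.0
    spike_width_ms: float = 1.0
    mains_amp: float = 0.3
    lfp_noise: float = 0.15
    lfp_polarity: int = 1
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if not self.up_mV > self.down_mV:
            raise ValueError("up_mV must exceed down_mV")
        if self.spike_rate_gain > 0 and self.fs < 500.0:
            raise ValueError("fs must be >= 500 Hz when spikes are enabled")


def _resample_to(trace_t: np.ndarray, values: np.ndarray, fs: float,
                 duration: float) -> Tuple[np.ndarray, np.ndarray]:
    t_out = np.arange(int(round(duration * fs))) / fs
    return t_out, np.interp(t_out, trace_t, values)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with 1/f power above ~0.01 Hz-equivalent bins."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _spike_times(trace: SimTrace, gain: float, theta_E: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson times with rate gain*max(E - theta_E, 0)."""
    rate = gain * np.clip(trace.E - theta_E, 0.0, None)   # spikes/s
    dt = trace.record_dt_s
    draws = rng.random(len(rate))
    hit = draws < rate * dt
    return trace.t[hit]


def render_vm(trace: SimTrace, cfg: RenderConfig = RenderConfig(),
              seed: int = 0) -> Recording:
    """Render the efferent activity as an intracellular V_m recording.

    The affine map sends E=0 to ``down_mV`` and the network's adapted Up
    fixed-point activity to ``up_mV``; the map is exactly invertible when
    noise, spikes and mains are disabled.
    """
    if len(trace.t) == 0:
        raise ValueError("empty trace")
    rng = np.random.default_rng(seed)
    rep = fixed_points(trace.params, adaptation_mode="self-consistent",
                       check_numeric=False)
    if rep.up is None:
        raise ValueError("no Up fixed point: cannot scale the mV map")
    e_up = rep.up[0]
    t, e = _resample_to(trace.t, trace.E, cfg.fs, trace.duration)
    vm = cfg.down_mV + (cfg.up_mV - cfg.down_mV) * e / e_up
    if cfg.obs_noise_mV > 0:
        vm = vm + cfg.obs_noise_mV * rng.standard_normal(len(vm))
    if cfg.mains_amp > 0:
        vm = vm + cfg.mains_amp * np.sin(2 * np.pi * 50.0 * t)
    spike_times = np.empty(0)
    if cfg.spike_rate_gain > 0:
        if cfg.fs < 2.0 * 1000.0 / cfg.spike_width_ms:
            raise ValueError("fs below Nyquist for spike insertion")
        spike_times = _spike_times(trace, cfg.spike_rate_gain,
                                   trace.params.theta_E, rng)
        half = int(round(cfg.spike_width_ms / 2000.0 * cfg.fs))
        half = max(half, 1)
        kernel = cfg.spike_amp_mV * (1.0 - np.abs(np.arange(-half, half + 1))
                                     / half)
        for ts in spike_times:
            i = int(round(ts * cfg.fs))
            lo, hi = i - half, i + half + 1
            klo, khi = max(0, -lo), len(kernel) - max(0, hi - len(vm))
            vm[max(lo, 0):min(hi, len(vm))] += kernel[klo:khi]
    return Recording(signal=vm, fs=cfg.fs, role="vm",
                     truth_spikes=spike_times)


def render_lfp(afferent_trace: SimTrace, cfg: RenderConfig = RenderConfig(),
               seed: int = 0) -> Recording:
    """Render the afferent activity as a z-scored LFP channel."""
    if len(afferent_trace.t) == 0:
        raise ValueError("empty trace")
    rng = np.random.default_rng(seed)
    t, e = _resample_to(afferent_trace.t, afferent_trace.E, cfg.fs,
                        afferent_trace.duration)
    sd = e.std()
    lfp = cfg.lfp_polarity * (e - e.mean()) / (sd if sd > 0 else 1.0)
    if cfg.lfp_noise > 0:
        lfp = lfp + cfg.lfp_noise * _pink_noise(len(lfp), rng)
    if cfg.mains_amp > 0:
        lfp = lfp + cfg.mains_amp * np.sin(2 * np.pi * 50.0 * t)
    return Recording(signal=lfp, fs=cfg.fs, role="lfp")


@dataclass
class CellRecording:
    """One surrogate cell: paired V_m/LFP with full ground truth."""

    cell_id: str
    vm: Recording
    lfp: Recording
    w_ext: float
    w_int: float
    seed: int


def _insert_desync(vm: Recording, lfp: Recording, interval: Tuple[float, float],
                   rng: np.random.Generator) -> None:
    """Replace both channels on [start, end) by low-amplitude 1/f noise.

    The surrogate desynchronized state suppresses 0.05-2 Hz power by
    replacing the UDS-locked waveform with pink noise at 20% of each
    channel's UDS amplitude, crossfaded over 0.5 s to avoid step edges.
    """
    for rec in (vm, lfp):
        i0 = int(interval[0] * rec.fs)
        i1 = int(interval[1] * rec.fs)
        i0, i1 = max(i0, 0), min(i1, len(rec.signal))
        if i1 <= i0:
            continue
        seg = rec.signal[i0:i1]
        amp = 0.2 * rec.signal.std()
        noise = rec.signal.mean() + amp * _pink_noise(len(seg), rng)
        ramp_n = min(int(0.5 * rec.fs), len(seg) // 4)
        w = np.ones(len(seg))
        if ramp_n > 0:
            w[:ramp_n] = np.linspace(0, 1, ramp_n)
            w[-ramp_n:] = np.linspace(1, 0, ramp_n)
        rec.signal[i0:i1] = (1 - w) * seg + w * noise


def make_cell_dataset(truth_list: Sequence[Tuple[float, float]],
                      duration: float = 400.0,
                      cfg: RenderConfig = RenderConfig(),
                      params: Optional[ModelParams] = None,
                      seed: int = 0, dt: float = 0.2,
                      record_every: int = 25,
                      desync_interval: Optional[Tuple[float, float]] = None
                      ) -> List[CellRecording]:
    """Simulate and render one paired recording per (W_EXT, W_INT) truth.

    Each cell gets an independent coupled simulation (derived seeds), V_m
    rendered from the efferent network and LFP from the afferent one, with
    the hysteresis-labelled ground-truth state sequences attached.  When
    ``desync_interval`` is given, that span of every pair is replaced by a
    desynchronized (1/f) epoch recorded in ``truth_desync``.
    """
    if len(truth_list) == 0:
        raise ValueError("truth_list must not be empty")
    params = params or ModelParams()
    out = []
    for c, (w_ext, w_int) in enumerate(truth_list):
        cell_seed = derive_seed(seed, c)
        ct = simulate_coupled(params, params.with_(W_EE=w_int), w_ext,
                              duration, dt=dt, seed=cell_seed,
                              record_every=record_every)
        vm = render_vm(ct.efferent, cfg, seed=derive_seed(cell_seed, 10))
        lfp = render_lfp(ct.afferent, cfg, seed=derive_seed(cell_seed, 11))
        vm.truth = binarize_states(ct.efferent)
        lfp.truth = binarize_states(ct.afferent)
        vm.truth_weights = (w_ext, w_int)
        lfp.truth_weights = (w_ext, w_int)
        if desync_interval is not None:
            rng = np.random.default_rng(derive_seed(cell_seed, 12))
            _insert_desync(vm, lfp, desync_interval, rng)
            epochs = EpochSet([tuple(desync_interval)],
                              label="desynchronized")
            vm.truth_desync = epochs
            lfp.truth_desync = epochs
        out.append(CellRecording(cell_id=f"cell{c:03d}", vm=vm, lfp=lfp,
                                 w_ext=w_ext, w_int=w_int, seed=cell_seed))
    return out
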